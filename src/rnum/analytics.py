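"""R-code analytics: histograms, per-residue traces, class matrices, time series.

An "R-code" is a histogram of normalised R values over a set of residues,
optionally peak-normalised so the tallest bar is unity — a bar-code-like
assay of a structure's geometric content.  Traces hold R per residue and
per trajectory frame, and can be windowed into a time series of R-codes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codec import DihedralPair, GridSpec, default_grid, encode_many, rama_number

__all__ = [
    "RCode",
    "rcode",
    "class_rcode_matrix",
    "ResidueTraceMatrix",
    "residue_trace",
    "rcode_timeseries",
    "alternation_score",
    "DensityRegion",
    "density_region",
    "MotifRegion",
    "motif_landmarks",
    "plot_rcode",
    "plot_trace_heatmap",
]

DEFAULT_BIN_WIDTH = 0.01


def _n_bins(bin_width: float) -> int:
    n = 1.0 / bin_width
    if not bin_width > 0 or abs(n - round(n)) > 1e-9:
        raise ValueError(f"bin_width must evenly divide 1, got {bin_width}")
    return int(round(n))


@dataclass
class RCode:
    """A binned histogram of R values over [0, 1)."""

    bin_width: float
    counts: np.ndarray  # integer counts per bin
    heights: np.ndarray | None = None  # peak-normalised, max == 1 (if normalised)

    @property
    def edges(self) -> np.ndarray:
        n = len(self.counts)
        return np.linspace(0.0, 1.0, n + 1)

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(len(self.counts)) + 0.5) * self.bin_width

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def peak_center(self) -> float:
        """Center of the highest bin; ties resolved toward the lowest r."""
        idx = int(np.argmax(self.counts))  # argmax returns the first maximum
        return float(self.centers[idx])


def _bin_indices(r: np.ndarray, bin_width: float) -> np.ndarray:
    n = _n_bins(bin_width)
    if np.any((r < 0.0) | (r > 1.0)):
        raise ValueError("r values must lie in [0, 1]")
    # left-closed bins; r == 1.0 (only reachable at the excluded corner)
    # is clamped into the last bin
    return np.minimum((r / bin_width).astype(np.int64), n - 1)


def rcode(
    r_values, bin_width: float = DEFAULT_BIN_WIDTH, normalize: bool = False
) -> RCode:
    """Histogram R values into left-closed bins of width ``bin_width``.

    Counts always sum to the number of (finite) input values.  With
    ``normalize`` the heights are scaled so the tallest bar is exactly 1;
    an empty input yields an all-zero RCode and normalisation is skipped.
    """
    n = _n_bins(bin_width)
    r = np.asarray(r_values, dtype=np.float64).ravel()
    r = r[np.isfinite(r)]
    counts = np.zeros(n, dtype=np.int64)
    if r.size:
        np.add.at(counts, _bin_indices(r, bin_width), 1)
    heights = None
    if normalize and counts.max() > 0:
        heights = counts / counts.max()
    return RCode(bin_width=bin_width, counts=counts, heights=heights)


def class_rcode_matrix(
    groups: Mapping[str, Sequence[float]], bin_width: float = DEFAULT_BIN_WIDTH
) -> pd.DataFrame:
    """One peak-normalised R-code column per class, on shared bins.

    Returns a DataFrame indexed by bin center, columns in input order.
    Empty classes produce an all-zero column and a warning.
    """
    if not groups:
        raise ValueError("need at least one class")
    columns = {}
    centers = None
    for label, values in groups.items():
        code = rcode(values, bin_width=bin_width, normalize=True)
        if code.total == 0:
            warnings.warn(f"class {label!r} has no residues; column left at zero", stacklevel=2)
            columns[label] = np.zeros(len(code.counts))
        else:
            columns[label] = code.heights
        centers = code.centers
    return pd.DataFrame(columns, index=pd.Index(centers, name="r_center"))


@dataclass
class ResidueTraceMatrix:
    """R per residue (rows) and per frame/model (columns); NaN = undefined."""

    values: np.ndarray  # shape (n_residues, n_frames)
    residue_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("trace values must be 2-D (residues x frames)")

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[f"frame{j}" for j in range(self.n_frames)]
        )
        df.insert(0, "residue", np.arange(self.n_residues))
        return df


def _phi_psi(item) -> tuple:
    if hasattr(item, "phi") and hasattr(item, "psi"):
        return item.phi, item.psi
    phi, psi = item
    return phi, psi


def _res_identity(item, index: int):
    if hasattr(item, "res_id"):
        return item.res_id
    return index


def residue_trace(frames: Sequence[Sequence], grid: GridSpec | None = None) -> ResidueTraceMatrix:
    """Per-residue R across one or more conformers of the same molecule.

    ``frames`` is a sequence over models; each model is a sequence of
    per-residue dihedral records (anything with ``phi``/``psi``
    attributes, e.g. :class:`~rnum.io.DihedralRecord`) or plain
    ``(phi, psi)`` pairs.  All frames must describe the same residue set,
    in the same order; a mismatch is rejected.  Residues with an
    undefined phi or psi get NaN.
    """
    grid = grid or default_grid()
    frames = [list(f) for f in frames]
    if not frames:
        raise ValueError("need at least one frame")
    ids0 = [_res_identity(item, i) for i, item in enumerate(frames[0])]
    for j, frame in enumerate(frames[1:], start=1):
        ids = [_res_identity(item, i) for i, item in enumerate(frame)]
        if ids != ids0:
            raise ValueError(
                f"frame {j} residue set differs from frame 0; "
                "trajectory frames must be conformers of one molecule"
            )
    n_res = len(ids0)
    values = np.full((n_res, len(frames)), np.nan)
    for j, frame in enumerate(frames):
        phi = np.array(
            [np.nan if (p := _phi_psi(it)[0]) is None else float(p) for it in frame]
        )
        psi = np.array(
            [np.nan if (p := _phi_psi(it)[1]) is None else float(p) for it in frame]
        )
        _, r = encode_many(phi, psi, grid)
        values[:, j] = r
    return ResidueTraceMatrix(values=values, residue_ids=ids0)


def rcode_timeseries(
    trace: ResidueTraceMatrix,
    frame_bin: int,
    bin_width: float = DEFAULT_BIN_WIDTH,
    normalize: bool = False,
) -> list[RCode]:
    """R-code per consecutive window of ``frame_bin`` frames.

    Windows are non-overlapping and left-aligned; a trailing partial
    window is kept.  Each window pools all defined residue cells it spans.
    """
    if frame_bin < 1:
        raise ValueError("frame_bin must be >= 1")
    codes = []
    for start in range(0, trace.n_frames, frame_bin):
        window = trace.values[:, start : start + frame_bin]
        codes.append(rcode(window[np.isfinite(window)], bin_width=bin_width, normalize=normalize))
    return codes


def alternation_score(r_sequence, delta: float = 0.05) -> float:
    """Fraction of consecutive residue triplets whose R zig-zags.

    A triplet (i-1, i, i+1) counts as alternating when the two successive
    differences have opposite signs and both magnitudes exceed ``delta``.
    Quantifies the two-state zig-zag signature of a Sigma-strand trace.

    Raises
    ------
    ValueError
        If fewer than 3 consecutive defined values exist (score undefined).
    """
    r = np.array(
        [np.nan if v is None else float(v) for v in r_sequence], dtype=np.float64
    )
    hits = 0
    total = 0
    for i in range(1, len(r) - 1):
        window = r[i - 1 : i + 2]
        if not np.all(np.isfinite(window)):
            continue
        d1 = window[1] - window[0]
        d2 = window[2] - window[1]
        total += 1
        if d1 * d2 < 0 and abs(d1) > delta and abs(d2) > delta:
            hits += 1
    if total == 0:
        raise ValueError("alternation score needs >= 3 consecutive defined R values")
    return hits / total


@dataclass
class DensityRegion:
    """Highest-density (phi, psi) cells enclosing a requested mass fraction."""

    mask: np.ndarray  # boolean, shape (n_cells_phi, n_cells_psi)
    phi_edges: np.ndarray
    psi_edges: np.ndarray
    contained_fraction: float

    @property
    def cells(self) -> list[tuple]:
        return [tuple(ij) for ij in np.argwhere(self.mask)]


def density_region(phi, psi, mass: float = 0.7, cell: float = 5.0) -> DensityRegion:
    """Smallest set of highest-density grid cells holding >= ``mass`` of points.

    Uses a fixed grid of ``cell``-degree squares over [-180, 180)^2.
    Ties between equally occupied cells are broken deterministically by
    cell index.  ``mass`` = 1 returns every occupied cell.
    """
    if not 0.0 < mass <= 1.0:
        raise ValueError("mass must be in (0, 1]")
    phi = np.asarray(phi, dtype=np.float64).ravel()
    psi = np.asarray(psi, dtype=np.float64).ravel()
    ok = np.isfinite(phi) & np.isfinite(psi)
    phi, psi = phi[ok], psi[ok]
    if phi.size < 10:
        raise ValueError("need at least 10 samples")
    n_cells = 360.0 / cell
    if abs(n_cells - round(n_cells)) > 1e-9:
        raise ValueError("cell size must divide 360")
    n_cells = int(round(n_cells))
    edges = np.linspace(-180.0, 180.0, n_cells + 1)
    wrap = lambda a: (a + 180.0) % 360.0 - 180.0
    counts, _, _ = np.histogram2d(wrap(phi), wrap(psi), bins=[edges, edges])
    flat = counts.ravel()
    order = np.lexsort((np.arange(flat.size), -flat))  # by count desc, then index
    cum = np.cumsum(flat[order])
    needed = mass * flat.sum()
    k = int(np.searchsorted(cum, needed - 1e-9) + 1)
    chosen = order[:k]
    chosen = chosen[flat[chosen] > 0]
    mask = np.zeros(flat.size, dtype=bool)
    mask[chosen] = True
    mask = mask.reshape(counts.shape)
    return DensityRegion(
        mask=mask,
        phi_edges=edges,
        psi_edges=edges,
        contained_fraction=float(flat[chosen].sum() / flat.sum()),
    )


@dataclass(frozen=True)
class MotifRegion:
    """A named landmark on the R line, with an interval and optional (phi, psi)."""

    name: str
    r_center: float
    r_interval: tuple
    phi_psi_center: DihedralPair | None = None


#: Conventional textbook (phi, psi) centers used for the derived landmarks.
_PPII_CENTER = DihedralPair(-75.0, 145.0)
_ALPHA_L_CENTER = DihedralPair(63.0, 43.0)


def motif_landmarks(
    width: float = 0.03, sigma_state: DihedralPair | None = None
) -> list[MotifRegion]:
    """Default landmarks on the R line.

    alpha (R ~ 0.36), beta (R ~ 0.52) and loop (R ~ 0.62) are the
    empirical protein-dataset landmarks; polyproline-II and left-handed
    alpha are derived from conventional (phi, psi) centers.  Passing a
    ``sigma_state`` (phi0, psi0) adds the two twist-opposed Sigma-strand
    states at r0 and 1 - r0.  Intervals are ``center +/- width`` and may
    overlap.
    """

    def region(name, center, pair=None):
        return MotifRegion(
            name=name,
            r_center=round(center, 6),
            r_interval=(center - width, center + width),
            phi_psi_center=pair,
        )

    landmarks = [
        region("alpha", 0.36, DihedralPair(-63.0, -43.0)),
        region("beta", 0.52, DihedralPair(-135.0, 135.0)),
        region("loop", 0.62),
        region("ppII", float(rama_number(*_PPII_CENTER)), _PPII_CENTER),
        region("alphaL", float(rama_number(*_ALPHA_L_CENTER)), _ALPHA_L_CENTER),
    ]
    if sigma_state is not None:
        phi0, psi0 = sigma_state
        r0 = float(rama_number(phi0, psi0))
        landmarks.append(region("sigma_state_1", r0, DihedralPair(phi0, psi0)))
        landmarks.append(region("sigma_state_2", 1.0 - r0, DihedralPair(-phi0, -psi0)))
    return landmarks


def plot_rcode(code: RCode, ax=None, **bar_kwargs):
    """Bar plot of an R-code (peak-normalised heights when available)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots()
    y = code.heights if code.heights is not None else code.counts
    ax.bar(code.centers, y, width=code.bin_width, align="center", **bar_kwargs)
    ax.set_xlabel("R")
    ax.set_xlim(0, 1)
    return ax


def plot_trace_heatmap(trace: ResidueTraceMatrix, ax=None, **imshow_kwargs):
    """Heat map of R per residue (y) and frame (x)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots()
    kwargs = dict(aspect="auto", origin="lower", vmin=0.0, vmax=1.0)
    kwargs.update(imshow_kwargs)
    im = ax.imshow(trace.values, **kwargs)
    ax.set_xlabel("frame")
    ax.set_ylabel("residue")
    return im
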