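"""Forward and inverse mapping between backbone dihedral pairs and a scalar index.

The (phi, psi) plane is rotated clockwise by 45 degrees, shifted into the
non-negative quadrant, rescaled by a grid resolution ``sigma`` (reciprocal
degrees) and raster-indexed row by row.  The resulting integer ``rz``
collapses the two dihedral angles into a single number that grows with
phi + psi, i.e. sweeps from right-handed twist across the untwisted
diagonal to left-handed twist while backbone extension changes as slowly
as possible.  ``r`` is ``rz`` normalised into [0, 1).

A true 45-degree rotation scales coordinates by 1/sqrt(2).  With
``lam = 360`` the integer grid coordinates are::

    phi' = round((phi - psi + lam) * sigma / sqrt(2))
    psi' = round((phi + psi + lam) * sigma / sqrt(2))

the row stride is ``lam' = round(sqrt(2) * lam * sigma)``, and::

    rz     = phi' + lam' * psi'
    rz_min = round(lam * sigma / sqrt(2))      # rz at (-180, -180)
    rz_max = rz_min + lam' ** 2                # rz at the excluded (180, 180)

Only the 1/sqrt(2) scaling is self-consistent: psi' evaluated at
(180, 180) must equal the row stride for the corner identity
``rz(180, 180) = rz(-180, -180) + lam'**2`` to hold.

Rounding is nearest-integer with half-away-from-zero ties (all rounded
quantities here are non-negative, so this equals half-up).  The inverse
map uses floor division and the matching non-negative remainder::

    phi ~ (rz // lam' + rz % lam') / (sqrt(2) * sigma) - lam
    psi ~ (rz // lam' - rz % lam') / (sqrt(2) * sigma)

and recovers each angle to within 1/sigma degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Union

import numpy as np

__all__ = [
    "SQRT2",
    "LAMBDA",
    "DEFAULT_SIGMA",
    "DihedralPair",
    "GridSpec",
    "RotatedCoords",
    "RamaNumber",
    "wrap_angle",
    "make_grid",
    "default_grid",
    "rotate_to_grid",
    "encode_rz",
    "decode_dihedrals",
    "encode_many",
    "decode_many",
    "rama_number",
    "twist_sense",
]

SQRT2 = math.sqrt(2.0)

#: Full angular range of each dihedral axis, in degrees.
LAMBDA = 360.0

#: Default grid resolution in reciprocal degrees; fine enough that the
#: round-trip error is far below coordinate uncertainty in the PDB.
DEFAULT_SIGMA = 1.0e5


class DihedralPair(NamedTuple):
    """A (phi, psi) backbone dihedral pair in degrees."""

    phi: float
    psi: float


class RotatedCoords(NamedTuple):
    """Integer grid coordinates after the rotate/shift/rescale transform."""

    phi_prime: int
    psi_prime: int


def _nearest_int(x: float) -> int:
    """Nearest integer, ties away from zero (half-up for non-negative x)."""
    if x >= 0.0:
        return int(math.floor(x + 0.5))
    return int(math.ceil(x - 0.5))


def wrap_angle(theta: float) -> float:
    """Wrap an angle in degrees into the canonical domain [-180, 180).

    +180 maps to -180 (the domain is half-open at the top).

    Raises
    ------
    ValueError
        If ``theta`` is NaN or infinite.
    """
    theta = float(theta)
    if not math.isfinite(theta):
        raise ValueError(f"angle must be finite, got {theta!r}")
    return (theta + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class GridSpec:
    """Parameters of the discretisation grid at resolution ``sigma``.

    ``lam_prime``, ``rz_min`` and ``rz_max`` are derived deterministically
    from ``sigma``; construct instances through :func:`make_grid`.
    """

    sigma: float
    lam: float
    lam_prime: int
    rz_min: int
    rz_max: int

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and math.isfinite(self.sigma)):
            raise ValueError(f"sigma must be a positive finite number, got {self.sigma!r}")
        if self.rz_min >= self.rz_max:
            raise ValueError("rz_min must be < rz_max")

    @property
    def span(self) -> int:
        """rz_max - rz_min (= lam_prime squared)."""
        return self.rz_max - self.rz_min


def make_grid(sigma: float = DEFAULT_SIGMA) -> GridSpec:
    """Build the :class:`GridSpec` for a grid resolution ``sigma`` > 0."""
    sigma = float(sigma)
    if not (sigma > 0 and math.isfinite(sigma)):
        raise ValueError(f"sigma must be a positive finite number, got {sigma!r}")
    lam_prime = _nearest_int(SQRT2 * LAMBDA * sigma)
    rz_min = _nearest_int(LAMBDA * sigma / SQRT2)
    rz_max = rz_min + lam_prime * lam_prime
    return GridSpec(sigma=sigma, lam=LAMBDA, lam_prime=lam_prime, rz_min=rz_min, rz_max=rz_max)


_DEFAULT_GRID: GridSpec | None = None


def default_grid() -> GridSpec:
    """The shared grid at :data:`DEFAULT_SIGMA` (built lazily, cached)."""
    global _DEFAULT_GRID
    if _DEFAULT_GRID is None:
        _DEFAULT_GRID = make_grid(DEFAULT_SIGMA)
    return _DEFAULT_GRID


@dataclass(frozen=True)
class RamaNumber:
    """An encoded dihedral pair: integer index ``rz`` and normalised ``r``."""

    rz: int
    r: float
    grid: GridSpec

    def __post_init__(self) -> None:
        if not (self.grid.rz_min <= self.rz <= self.grid.rz_max):
            raise ValueError(f"rz={self.rz} outside [{self.grid.rz_min}, {self.grid.rz_max}]")


def _as_pair(d) -> DihedralPair:
    if isinstance(d, DihedralPair):
        return d
    phi, psi = d
    return DihedralPair(float(phi), float(psi))


def rotate_to_grid(d, grid: GridSpec | None = None) -> RotatedCoords:
    """Map a canonicalised (phi, psi) pair onto the integer grid."""
    grid = grid or default_grid()
    phi, psi = _as_pair(d)
    phi = wrap_angle(phi)
    psi = wrap_angle(psi)
    scale = grid.sigma / SQRT2
    return RotatedCoords(
        phi_prime=_nearest_int((phi - psi + grid.lam) * scale),
        psi_prime=_nearest_int((phi + psi + grid.lam) * scale),
    )


def encode_rz(d, grid: GridSpec | None = None) -> RamaNumber:
    """Encode a (phi, psi) pair into its scalar index.

    The integer ``rz`` is clamped into [rz_min, rz_max]: grid rounding can
    otherwise push inputs infinitesimally close to the excluded (180, 180)
    corner one cell past the top of the range.
    """
    grid = grid or default_grid()
    rc = rotate_to_grid(d, grid)
    rz = rc.phi_prime + grid.lam_prime * rc.psi_prime
    rz = min(max(rz, grid.rz_min), grid.rz_max)
    r = (rz - grid.rz_min) / grid.span
    return RamaNumber(rz=rz, r=r, grid=grid)


def decode_dihedrals(rn: Union[RamaNumber, int], grid: GridSpec | None = None) -> DihedralPair:
    """Recover the closest approximation to the (phi, psi) pair behind ``rz``.

    Accepts either a :class:`RamaNumber` (its own grid is used) or a bare
    integer ``rz`` together with ``grid``.  The recovered angles differ
    from the originals by at most 1/sigma degrees (modulo 360).
    """
    if isinstance(rn, RamaNumber):
        grid = rn.grid
        rz = rn.rz
    else:
        grid = grid or default_grid()
        rz = int(rn)
    if not (grid.rz_min <= rz <= grid.rz_max):
        raise ValueError(f"rz={rz} outside [{grid.rz_min}, {grid.rz_max}]")
    q, rem = divmod(rz, grid.lam_prime)
    denom = SQRT2 * grid.sigma
    phi = (q + rem) / denom - grid.lam
    psi = (q - rem) / denom
    return DihedralPair(phi, psi)


def encode_many(phi, psi, grid: GridSpec | None = None):
    """Vectorised encode: arrays of degrees -> (rz int64 array, r float array).

    NaN inputs propagate to NaN in ``r`` and a sentinel -1 in ``rz``.
    """
    grid = grid or default_grid()
    phi = np.asarray(phi, dtype=np.float64)
    psi = np.asarray(psi, dtype=np.float64)
    ok = np.isfinite(phi) & np.isfinite(psi)
    w_phi = (phi + 180.0) % 360.0 - 180.0
    w_psi = (psi + 180.0) % 360.0 - 180.0
    scale = grid.sigma / SQRT2
    with np.errstate(invalid="ignore"):
        pp = np.floor((w_phi - w_psi + grid.lam) * scale + 0.5)
        sp = np.floor((w_phi + w_psi + grid.lam) * scale + 0.5)
    rz = np.where(ok, pp, 0.0).astype(np.int64) + grid.lam_prime * np.where(ok, sp, 0.0).astype(np.int64)
    rz = np.clip(rz, grid.rz_min, grid.rz_max)
    r = (rz - grid.rz_min) / grid.span
    r = np.where(ok, r, np.nan)
    rz = np.where(ok, rz, -1)
    return rz, r


def decode_many(rz, grid: GridSpec | None = None):
    """Vectorised inverse of :func:`encode_many` -> (phi, psi) arrays."""
    grid = grid or default_grid()
    rz = np.asarray(rz, dtype=np.int64)
    if np.any((rz < grid.rz_min) | (rz > grid.rz_max)):
        raise ValueError("rz values outside grid range")
    q, rem = np.divmod(rz, np.int64(grid.lam_prime))
    denom = SQRT2 * grid.sigma
    phi = (q + rem) / denom - grid.lam
    psi = (q - rem) / denom
    return phi, psi


def rama_number(phi, psi, sigma: float = DEFAULT_SIGMA):
    """Normalised Ramachandran number(s) for degrees ``phi``, ``psi``.

    Convenience wrapper around :func:`encode_many`; returns a scalar for
    scalar input, else an ndarray.
    """
    grid = default_grid() if sigma == DEFAULT_SIGMA else make_grid(sigma)
    _, r = encode_many(phi, psi, grid)
    if np.ndim(r) == 0:
        return float(r)
    return r


def twist_sense(d) -> str:
    """Local backbone twist sense of a dihedral pair.

    ``'D'`` (right-handed) below the negative-sloping diagonal
    (phi + psi < 0), ``'L'`` (left-handed) above it, ``'boundary'`` on it.
    """
    phi, psi = _as_pair(d)
    s = wrap_angle(phi) + wrap_angle(psi)
    if s < 0.0:
        return "D"
    if s > 0.0:
        return "L"
    return "boundary"
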