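"""Seeded synthetic inputs: motif ensembles, Sigma-strand chains, trajectories.

Everything here is a pure function of its parameters and seed, so tests
and the acceptance pipeline run without any external data.  Motif centers
are conventional textbook values, with isotropic Gaussian angular noise
wrapped into the canonical domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .codec import DihedralPair, wrap_angle

__all__ = [
    "MotifSpec",
    "MOTIF_CENTERS",
    "motif",
    "sample_motif",
    "sample_mixed_dihedrals",
    "constant_chain",
    "make_sigma_chain",
    "make_trajectory",
    "trajectory_to_pdb",
]

#: Conventional (phi, psi) centers in degrees; package defaults, not fitted values.
MOTIF_CENTERS = {
    "alpha": (-63.0, -43.0),
    "beta": (-135.0, 135.0),
    "ppII": (-75.0, 145.0),
    "alphaL": (63.0, 43.0),
}

DEFAULT_SPREAD = 10.0


@dataclass(frozen=True)
class MotifSpec:
    """A motif as a (phi, psi) center with isotropic angular spread (degrees)."""

    name: str
    phi: float
    psi: float
    spread: float = DEFAULT_SPREAD

    def __post_init__(self) -> None:
        if self.spread < 0:
            raise ValueError("spread must be >= 0")

    @property
    def center(self) -> DihedralPair:
        return DihedralPair(wrap_angle(self.phi), wrap_angle(self.psi))


def motif(name: str, spread: float = DEFAULT_SPREAD) -> MotifSpec:
    """A :class:`MotifSpec` for one of the named default centers."""
    phi, psi = MOTIF_CENTERS[name]
    return MotifSpec(name=name, phi=phi, psi=psi, spread=spread)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_motif(spec: MotifSpec, n: int, seed=0) -> list[DihedralPair]:
    """``n`` Gaussian (phi, psi) samples around the motif center, wrapped."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    phi = spec.phi + spec.spread * rng.standard_normal(n)
    psi = spec.psi + spec.spread * rng.standard_normal(n)
    return [DihedralPair(wrap_angle(p), wrap_angle(q)) for p, q in zip(phi, psi)]


def sample_mixed_dihedrals(
    n_residues: int,
    seed=0,
    motifs: Sequence[MotifSpec] | None = None,
    weights: Sequence[float] | None = None,
) -> list[DihedralPair]:
    """Per-residue dihedrals drawn iid from a mixture of motif Gaussians."""
    if motifs is None:
        motifs = [motif(name) for name in MOTIF_CENTERS]
    rng = _rng(seed)
    p = None
    if weights is not None:
        p = np.asarray(weights, dtype=float)
        p = p / p.sum()
    choices = rng.choice(len(motifs), size=n_residues, p=p)
    out = []
    for k in choices:
        out.extend(sample_motif(motifs[k], 1, rng))
    return out


def constant_chain(pair, n_residues: int) -> list[DihedralPair]:
    """A homogeneous chain with every residue at the same (phi, psi)."""
    phi, psi = pair
    return [DihedralPair(float(phi), float(psi))] * n_residues


def make_sigma_chain(state, n_residues: int, noise_sd: float = 0.0, seed=0) -> list[DihedralPair]:
    """A two-state alternating chain: (phi0, psi0) on even residues,
    (-phi0, -psi0) on odd, plus optional Gaussian angular noise.

    The two states are twist-opposed mirrors, so the chain's R trace
    alternates symmetrically about 0.5.
    """
    if n_residues < 3:
        raise ValueError("a Sigma-strand chain needs at least 3 residues")
    phi0, psi0 = state
    rng = _rng(seed)
    out = []
    for i in range(n_residues):
        sign = 1.0 if i % 2 == 0 else -1.0
        phi = sign * phi0 + noise_sd * rng.standard_normal()
        psi = sign * psi0 + noise_sd * rng.standard_normal()
        out.append(DihedralPair(wrap_angle(phi), wrap_angle(psi)))
    return out


def make_trajectory(
    frame_fn: Callable[[np.random.Generator], Sequence[DihedralPair]],
    n_frames: int,
    seed=0,
    switch_frame: int = 0,
    frame_fn_after: Callable[[np.random.Generator], Sequence[DihedralPair]] | None = None,
) -> list[list[DihedralPair]]:
    """A multi-frame dihedral trajectory with an optional regime switch.

    Frames with index < ``switch_frame`` are drawn from ``frame_fn``,
    later frames from ``frame_fn_after`` (when given; with
    ``switch_frame`` = 0 the whole trajectory comes from it).  Each frame
    generator receives its own child generator spawned from the master
    seed, so the trajectory is reproducible frame by frame.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not 0 <= switch_frame <= n_frames:
        raise ValueError("switch_frame must be in [0, n_frames]")
    seq = np.random.SeedSequence(seed if not isinstance(seed, np.random.SeedSequence) else None)
    children = seq.spawn(n_frames)
    frames = []
    for i in range(n_frames):
        fn = frame_fn if (i < switch_frame or frame_fn_after is None) else frame_fn_after
        frames.append(list(fn(np.random.default_rng(children[i]))))
    return frames


def trajectory_to_pdb(frames, path, params=None) -> None:
    """Build each frame's backbone and write a multi-model PDB."""
    from .builder import IDEAL_GEOMETRY, build_chain
    from .io import write_pdb

    params = params or IDEAL_GEOMETRY
    chains = [build_chain(frame, params) for frame in frames]
    write_pdb(chains, path)
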