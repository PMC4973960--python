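"""Structure and label I/O: PDB backbones, dihedral extraction, DSSP output, R tables.

PDB parsing is delegated to Biopython; only the N/CA/C backbone atoms are
retained.  Dihedrals are measured with Biopython's ``calc_dihedral`` —
deliberately a different code path from the forward-kinematics builder,
so the two act as mutual checks.  Classic DSSP *output* files are parsed
here (the DSSP assignment algorithm itself is not reimplemented).
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.vectors import Vector, calc_dihedral

from .codec import GridSpec, default_grid, wrap_angle

__all__ = [
    "BackboneResidue",
    "ChainModel",
    "DihedralRecord",
    "SSLabel",
    "BOND_BREAK_DISTANCE",
    "read_pdb",
    "extract_dihedrals",
    "read_dssp",
    "write_pdb",
    "write_r_table",
    "read_r_table",
]

#: Consecutive residues are considered bonded iff C(i-1)-N(i) <= this (A).
BOND_BREAK_DISTANCE = 2.5

_COARSE_SS = {"H": "helix", "G": "helix", "I": "helix", "E": "sheet", "B": "sheet"}


def coarse_ss_class(dssp_code: str) -> str:
    """Map a one-letter DSSP code to {helix, sheet, loop}."""
    return _COARSE_SS.get(dssp_code, "loop")


@dataclass
class BackboneResidue:
    """One residue's backbone atoms; any atom may be missing (None)."""

    chain_id: str
    resseq: int
    icode: str
    resname: str
    n: np.ndarray | None = None
    ca: np.ndarray | None = None
    c: np.ndarray | None = None

    @property
    def complete(self) -> bool:
        return self.n is not None and self.ca is not None and self.c is not None

    @property
    def res_id(self) -> tuple:
        return (self.chain_id, self.resseq, self.icode)


@dataclass
class ChainModel:
    chain_id: str
    residues: list = field(default_factory=list)


@dataclass
class DihedralRecord:
    """Per-residue backbone dihedrals in degrees; None where undefined."""

    chain_id: str
    resseq: int
    icode: str
    resname: str
    phi: float | None = None
    psi: float | None = None
    omega: float | None = None
    model_index: int = 0

    @property
    def res_id(self) -> tuple:
        return (self.chain_id, self.resseq, self.icode)


@dataclass
class SSLabel:
    """A DSSP secondary-structure label for one residue."""

    chain_id: str
    resseq: int
    icode: str
    dssp_code: str
    ss_class: str

    @property
    def res_id(self) -> tuple:
        return (self.chain_id, self.resseq, self.icode)


def _atom_coord(residue, name: str) -> np.ndarray | None:
    """Backbone atom coordinate, resolving altlocs to highest occupancy (ties: 'A')."""
    if name not in residue:
        return None
    atom = residue[name]
    if atom.is_disordered():
        children = sorted(
            atom.disordered_get_list(),
            key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
        )
        atom = children[0]
    return np.asarray(atom.get_coord(), dtype=np.float64)


def read_pdb(path) -> list[list[ChainModel]]:
    """Parse a (possibly multi-model) PDB file into backbone-only models.

    Returns a list of models in file order; each model is a list of
    :class:`ChainModel` holding :class:`BackboneResidue` entries in file
    order.  Only standard-residue ATOM records contribute; a residue
    missing any of N/CA/C is kept but flagged incomplete.  A file that
    yields no polymer chains at all (e.g. HETATM-only) produces an empty
    model list with a warning.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("s", path)
    except Exception as exc:  # pragma: no cover - parser is permissive
        raise ValueError(f"cannot parse PDB file {path!r}: {exc}") from exc
    models: list[list[ChainModel]] = []
    for model in structure:
        chains: list[ChainModel] = []
        for chain in model:
            residues = []
            for res in chain:
                hetflag, resseq, icode = res.get_id()
                if hetflag.strip():
                    continue  # skip HETATM/water
                residues.append(
                    BackboneResidue(
                        chain_id=chain.id,
                        resseq=resseq,
                        icode=icode.strip(),
                        resname=res.get_resname(),
                        n=_atom_coord(res, "N"),
                        ca=_atom_coord(res, "CA"),
                        c=_atom_coord(res, "C"),
                    )
                )
            if residues:
                chains.append(ChainModel(chain_id=chain.id, residues=residues))
        models.append(chains)
    if not any(models):
        warnings.warn(f"no polymer chains found in {path!r}", stacklevel=2)
    return models


def model_from_chain(chain, chain_id: str = "A", resname: str = "GLY") -> list[ChainModel]:
    """Wrap a built :class:`~rnum.builder.BackboneChain` as an in-memory model.

    Bypasses the PDB text format (and its 0.001 A coordinate rounding), so
    extracted dihedrals can be compared against the builder's inputs at
    full precision.
    """
    residues = [
        BackboneResidue(
            chain_id=chain_id,
            resseq=i + 1,
            icode="",
            resname=resname,
            n=chain.coords[i, 0].copy(),
            ca=chain.coords[i, 1].copy(),
            c=chain.coords[i, 2].copy(),
        )
        for i in range(chain.n_residues)
    ]
    return [ChainModel(chain_id=chain_id, residues=residues)]


def _dihedral_deg(a, b, c, d) -> float:
    ang = math.degrees(calc_dihedral(Vector(*a), Vector(*b), Vector(*c), Vector(*d)))
    return wrap_angle(ang)


def extract_dihedrals(model: Sequence[ChainModel], model_index: int = 0) -> list[DihedralRecord]:
    """Compute per-residue (phi, psi, omega) for one parsed model.

    phi(i) uses C(i-1)-N(i)-CA(i)-C(i); psi(i) uses N(i)-CA(i)-C(i)-N(i+1);
    omega(i) uses CA(i-1)-C(i-1)-N(i)-CA(i).  An angle is emitted only when
    all four atoms exist and the residues involved are bonded
    (C(i-1)-N(i) distance <= ``BOND_BREAK_DISTANCE``); termini, chain
    breaks and incomplete residues yield None, never fabricated values.
    """
    records: list[DihedralRecord] = []
    for chain in model:
        rs = chain.residues
        bonded = [False] * len(rs)
        for i in range(1, len(rs)):
            prev, cur = rs[i - 1], rs[i]
            if prev.c is not None and cur.n is not None:
                bonded[i] = float(np.linalg.norm(cur.n - prev.c)) <= BOND_BREAK_DISTANCE
        for i, res in enumerate(rs):
            phi = psi = omega = None
            if (
                i > 0
                and bonded[i]
                and rs[i - 1].c is not None
                and res.n is not None
                and res.ca is not None
                and res.c is not None
            ):
                phi = _dihedral_deg(rs[i - 1].c, res.n, res.ca, res.c)
            if (
                i + 1 < len(rs)
                and bonded[i + 1]
                and res.n is not None
                and res.ca is not None
                and res.c is not None
                and rs[i + 1].n is not None
            ):
                psi = _dihedral_deg(res.n, res.ca, res.c, rs[i + 1].n)
            if (
                i > 0
                and bonded[i]
                and rs[i - 1].ca is not None
                and rs[i - 1].c is not None
                and res.n is not None
                and res.ca is not None
            ):
                omega = _dihedral_deg(rs[i - 1].ca, rs[i - 1].c, res.n, res.ca)
            records.append(
                DihedralRecord(
                    chain_id=res.chain_id,
                    resseq=res.resseq,
                    icode=res.icode,
                    resname=res.resname,
                    phi=phi,
                    psi=psi,
                    omega=omega,
                    model_index=model_index,
                )
            )
    return records


def read_dssp(path) -> list[SSLabel]:
    """Parse a classic DSSP output file into per-residue labels.

    Emits one :class:`SSLabel` per residue line; chain-break ``!`` lines
    produce no label.  Malformed residue lines are skipped and counted in
    a single summary warning.
    """
    labels: list[SSLabel] = []
    skipped = 0
    in_body = False
    with open(path) as fh:
        for line in fh:
            if not in_body:
                if line.lstrip().startswith("#") and "RESIDUE" in line and "AA" in line:
                    in_body = True
                continue
            if len(line) < 17:
                skipped += 1
                continue
            if line[13] == "!":
                continue
            try:
                resseq = int(line[5:10])
            except ValueError:
                skipped += 1
                continue
            icode = line[10].strip()
            chain_id = line[11].strip()
            code = line[16]
            code = code if code.strip() else " "
            labels.append(
                SSLabel(
                    chain_id=chain_id,
                    resseq=resseq,
                    icode=icode,
                    dssp_code=code,
                    ss_class=coarse_ss_class(code),
                )
            )
    if not in_body:
        raise ValueError(f"{path!r} does not look like DSSP output (no residue header)")
    if skipped:
        warnings.warn(f"{path!r}: skipped {skipped} malformed residue line(s)", stacklevel=2)
    return labels


_PDB_ATOM = (
    "ATOM  {serial:5d} {name:^4s}{alt:1s}{resname:>3s} {chain:1s}{resseq:4d}{icode:1s}"
    "   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bfac:6.2f}          {element:>2s}\n"
)


def write_pdb(chains, path, resname: str = "GLY", chain_id: str = "A") -> None:
    """Write built backbone chain(s) as a PDB file.

    ``chains`` is a single :class:`~rnum.builder.BackboneChain` or a
    sequence of them; multiple chains are written as successive MODEL
    records (the trajectory convention used throughout this package).
    """
    from .builder import BackboneChain  # local import to avoid a cycle

    if isinstance(chains, BackboneChain):
        frames = [chains]
    else:
        frames = list(chains)
    multi = len(frames) > 1
    lines: list[str] = []
    for midx, chain in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL     {midx:4d}\n")
        serial = 1
        for ridx in range(chain.n_residues):
            for name, element, pos in zip(
                ("N", "CA", "C"), ("N", "C", "C"), chain.coords[ridx]
            ):
                lines.append(
                    _PDB_ATOM.format(
                        serial=serial,
                        name=name,
                        alt=" ",
                        resname=resname,
                        chain=chain_id,
                        resseq=ridx + 1,
                        icode=" ",
                        x=pos[0],
                        y=pos[1],
                        z=pos[2],
                        occ=1.0,
                        bfac=0.0,
                        element=element,
                    )
                )
                serial += 1
        lines.append("TER\n")
        if multi:
            lines.append("ENDMDL\n")
    lines.append("END\n")
    tmp = os.fspath(path) + ".tmp"
    with open(tmp, "w") as fh:
        fh.writelines(lines)
    os.replace(tmp, path)


_R_TABLE_COLUMNS = ["model", "chain", "resseq", "icode", "resname", "phi", "psi", "omega", "r"]


def write_r_table(records: Sequence[DihedralRecord], path, grid: GridSpec | None = None) -> None:
    """Write per-residue dihedrals and their normalised R to a TSV file.

    One row per residue per model; undefined angles become empty fields.
    Floats carry 12 significant digits so a read-back round trip is exact
    to that precision.
    """
    from .codec import encode_many  # late import: keep module import light

    grid = grid or default_grid()
    rows = []
    for rec in records:
        if rec.phi is not None and rec.psi is not None:
            _, r = encode_many(rec.phi, rec.psi, grid)
            r = float(r)
        else:
            r = None
        rows.append(
            (
                rec.model_index,
                rec.chain_id,
                rec.resseq,
                rec.icode,
                rec.resname,
                rec.phi,
                rec.psi,
                rec.omega,
                r,
            )
        )
    df = pd.DataFrame(rows, columns=_R_TABLE_COLUMNS)
    tmp = os.fspath(path) + ".tmp"
    df.to_csv(tmp, sep="\t", index=False, float_format="%.12g", na_rep="")
    os.replace(tmp, path)


def read_r_table(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_r_table`."""
    return pd.read_csv(path, sep="\t", dtype={"icode": str, "chain": str}, keep_default_na=True)
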