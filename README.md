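# rnum

A scalar order parameter for protein and peptoid backbone geometry.

`rnum` collapses each backbone dihedral pair (φ, ψ) into a single
normalised *Ramachandran number* R ∈ [0, 1) by rotating the Ramachandran
plane 45° clockwise, discretising it at a resolution σ (reciprocal
degrees, default 10⁵) and raster-indexing the grid. The map is
invertible up to the grid spacing: angles are recovered from the integer
index to within 1/σ degrees, and rebuilt 3D backbones deviate far less
than the ~1 Å coordinate uncertainty typical of experimental structures.

On top of the codec the package provides:

- **`rnum.codec`** — forward encoding (φ, ψ) → rz → R, the inverse
  back-mapping, twist-sense classification, scalar and vectorised APIs.
- **`rnum.builder`** — deterministic internal-coordinate construction of
  N/Cα/C backbones from dihedral sequences, end-to-end distance and
  radius-of-gyration measures, full-plane end-to-end-distance maps,
  R-conditioned end-to-end statistics, and encode/decode/rebuild
  round-trip RMSD validation.
- **`rnum.io`** — PDB reading (single- and multi-model; Biopython-backed),
  backbone dihedral extraction with chain-break handling, classic DSSP
  output parsing, PDB writing for built chains, per-residue R tables.
- **`rnum.analytics`** — R histograms ("R-codes"), per-class R-code
  matrices, per-residue/per-frame R traces, windowed R-code time series,
  alternation scoring for two-state (Σ-strand-like) motifs, highest-density
  (φ, ψ) regions, and named landmarks on the R line
  (α ≈ 0.36, β ≈ 0.52, loop ≈ 0.62, …).
- **`rnum.fixtures`** — seeded generators for motif ensembles, mixed-motif
  chains, alternating two-state chains and multi-frame trajectories, so
  the entire pipeline runs without any external data.

## Quick start

```python
from rnum import encode_rz, decode_dihedrals, rama_number

rn = encode_rz((-63.0, -43.0))     # alpha-helical residue
rn.r                               # 0.3527777...
decode_dihedrals(rn)               # (-62.999998..., -43.000004...)
rama_number([-63, -135], [-43, 135])  # vectorised
```

End-to-end, from a structure file:

```python
from rnum import read_pdb, extract_dihedrals, rama_number
from rnum.analytics import rcode

model = read_pdb("structure.pdb")[0]
records = extract_dihedrals(model)
r = [rama_number(x.phi, x.psi) for x in records if x.phi is not None and x.psi is not None]
code = rcode(r, bin_width=0.01, normalize=True)   # the structure's R-code
```

## Command line

All functionality is exposed through a single `rnum` entry point:

```sh
rnum encode --phi -63 --psi -43            # print rz and R
rnum decode --rz 914400007305887           # back-map to (phi, psi)
rnum compute structure.pdb --dssp structure.dssp --out r_table.tsv
rnum rcode --table r_table.tsv --normalize --out rcode.tsv
rnum trace trajectory.pdb --out trace.tsv  # per-residue R per model
rnum timeseries trajectory.pdb --frame-bin 5 --out ts.tsv
rnum remap --n 20 --step 10 --out remap.tsv
rnum build --dihedrals angles.csv --out chain.pdb
rnum validate --sigma 1e5 --chains 20 --len 100 --seed 7
rnum fixtures motif --motif alpha --n 1000 --seed 1 --out angles.csv
rnum fixtures trajectory --frames 50 --switch 25 --out traj.pdb
```

Defaults (σ = 10⁵, bin width 0.01, ideal backbone geometry) can be set in
a TOML file passed with `--config`; explicit flags win over the file.
Table outputs start with `#` header lines echoing the effective
configuration.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes property tests (hypothesis), extended-precision oracle
comparisons for the codec, closed-form geometric oracles for the builder,
and `tests/test_acceptance.py` with one test per acceptance criterion.
The secondary-structure landmark test needs an external structure set and
is skipped unless `RNUM_LANDMARK_DATA` points at a directory of paired
`<name>.pdb` / `<name>.dssp` files.

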