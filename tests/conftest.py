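import numpy as np
import pytest

from rnum import builder, fixtures


@pytest.fixture(scope="session")
def alpha_chain():
    """A 10-residue homopolymer at the canonical alpha-helix center."""
    return builder.build_chain([(-63.0, -43.0, 180.0)] * 10)


@pytest.fixture(scope="session")
def mixed_chains():
    """Three seeded 30-residue mixed-motif dihedral sequences."""
    return [
        fixtures.sample_mixed_dihedrals(30, seed=np.random.default_rng([11, i]))
        for i in range(3)
    ]
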