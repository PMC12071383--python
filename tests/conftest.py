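import pytest

from mutpocket.depth import compute_residue_depths
from mutpocket.synthetic_data import make_helix_bundle, make_variant_fixture


ALA_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 90.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 92.00           C
ATOM      3  C   ALA A   1      12.776   7.076  -4.925  1.00 94.00           C
ATOM      4  O   ALA A   1      13.233   7.755  -5.846  1.00 91.00           O
ATOM      5  CB  ALA A   1      10.491   6.286  -4.151  1.00 90.00           C
END
"""


@pytest.fixture(scope="session")
def bundle():
    """Default helix-bundle fixture (deterministic, seed 0)."""
    structure, labels = make_helix_bundle(seed=0)
    return structure, labels


@pytest.fixture(scope="session")
def bundle_depths(bundle):
    structure, _ = bundle
    return compute_residue_depths(structure)


@pytest.fixture(scope="session")
def bundle_variants(bundle):
    structure, labels = bundle
    return make_variant_fixture(structure, labels, seed=0)
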