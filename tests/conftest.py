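import pytest

from ampedit.crispr_targeting import target_windows
from ampedit.synthetic_data import build_reference, design_tiling


@pytest.fixture(scope="session")
def reference():
    return build_reference()


@pytest.fixture(scope="session")
def genome(reference):
    return reference[0]


@pytest.fixture(scope="session")
def annotation(reference):
    return reference[1]


@pytest.fixture(scope="session")
def targets(reference):
    return reference[2]


@pytest.fixture(scope="session")
def scheme(genome):
    """The study-profile tiling: 400 bp amplicons, 100 bp insert overlap."""
    return design_tiling(genome, amplicon_len=400, overlap=100, primer_len=22)


@pytest.fixture(scope="session")
def windows(genome, targets):
    return target_windows(genome, targets)
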