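import pytest

from tarms import cvm
from tarms.fixtures import synth_locus

SEED = cvm.DEFAULT_SEED


@pytest.fixture(scope="session")
def cvm_locus():
    return cvm.cvm_locus()


@pytest.fixture(scope="session")
def modified_assay(cvm_locus):
    return cvm.cvm_assay("modified", locus=cvm_locus)


@pytest.fixture(scope="session")
def software_assay(cvm_locus):
    return cvm.cvm_assay("software", locus=cvm_locus)


@pytest.fixture(scope="session")
def small_locus():
    """A 600 nt synthetic locus with a central G>T SNP."""
    locus, wild_t, mut_t = synth_locus(length=600, snp_offset=300, seed=SEED)
    return locus, wild_t, mut_t
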