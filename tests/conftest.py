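import numpy as np
import pytest

from cnphap import presets
from cnphap.synthcohort import HaplotypeModel, haplotype_universe


@pytest.fixture(scope="session")
def gwas_model() -> HaplotypeModel:
    """Six-haplotype CPD model (GWAS-set frequencies and effects)."""
    return presets.cpd_gwas_model()


@pytest.fixture(scope="session")
def universe():
    return haplotype_universe()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
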