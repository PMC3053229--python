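import numpy as np
import pytest

from caninascope.canina_genetics import MeiosisConfig, make_founder
from caninascope.pyroseq_sim import AssayNoise, SNPAssay


@pytest.fixture
def cfg():
    return MeiosisConfig(seed=7)


@pytest.fixture
def leafy_founder():
    """Pentaploid with the duplicated allele on the bivalent pair and three
    distinct univalent alleles (the LEAFY-like configuration)."""
    return make_founder("LEAFY-3", ("LEAFY-1", "LEAFY-2", "LEAFY-4"), ["LEAFY"])


@pytest.fixture
def default_noise():
    return AssayNoise(read_depth=500, rho=0.005)


@pytest.fixture
def leafy_assays():
    """Three singleton-carrier assays over a four-allele locus; the fourth
    allele (no usable SNP) stays unassayed."""
    return [
        SNPAssay("LEAFY_SNP1", "LEAFY", 10, "G", frozenset({"LEAFY-3"})),
        SNPAssay("LEAFY_SNP2", "LEAFY", 40, "T", frozenset({"LEAFY-1"})),
        SNPAssay("LEAFY_SNP3", "LEAFY", 70, "A", frozenset({"LEAFY-4"})),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(11)
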