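import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ivmr import (
    InstrumentSpec,
    SummaryStats,
    VariantAssociation,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_variant(vid="rs1", ea="A", oa="G", beta=0.1, se=0.02, eaf=0.3, **kw):
    return VariantAssociation(vid, ea, oa, beta=beta, se=se, eaf=eaf, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def concordant_pair():
    """4-variant exposure/outcome tables already on the same effect alleles."""
    exposure = SummaryStats.from_records(
        [
            make_variant("rs1", "A", "G", beta=0.30, se=0.015, eaf=0.30),
            make_variant("rs2", "C", "T", beta=0.15, se=0.016, eaf=0.25),
            make_variant("rs3", "T", "G", beta=0.10, se=0.017, eaf=0.40),
            make_variant("rs4", "G", "A", beta=0.08, se=0.016, eaf=0.35),
        ]
    )
    outcome = SummaryStats.from_records(
        [
            make_variant("rs1", "A", "G", beta=0.060, se=0.008, eaf=0.31),
            make_variant("rs2", "C", "T", beta=0.030, se=0.008, eaf=0.24),
            make_variant("rs3", "T", "G", beta=0.022, se=0.009, eaf=0.41),
            make_variant("rs4", "G", "A", beta=0.015, se=0.008, eaf=0.34),
        ]
    )
    spec = InstrumentSpec("FA", ("rs1", "rs2", "rs3", "rs4"))
    return spec, exposure, outcome
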