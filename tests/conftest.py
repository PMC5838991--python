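import pytest

from escvar.model import Sift, VariantCall, VariantClass
from escvar.simulate import SyntheticConfig, generate_cohort


def make_variant(**overrides) -> VariantCall:
    """A valid baseline variant; override any field."""
    base = dict(
        patient_id="P01",
        chrom="chr1",
        pos=1000,
        ref="C",
        alt="T",
        gene="TP53",
        variant_class=VariantClass.missense,
        vaf=0.10,
        alt_reads=30,
        depth=300,
        cosmic=False,
        sift=Sift.missing,
    )
    base.update(overrides)
    return VariantCall(**base)


@pytest.fixture(scope="session")
def default_bundle():
    """One default 15-tumor / 53-normal synthetic cohort, shared per session."""
    return generate_cohort(SyntheticConfig(seed=1))
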