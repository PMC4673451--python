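import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from exomesift.model import CohortStudy, SampleCallset, VariantCall, VariantKey

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


GOOD_ANNOTATIONS = {
    "DP": 50,
    "QD": 12.0,
    "FS": 1.2,
    "MQ": 60.0,
    "HaplotypeScore": 0.5,
    "MQRankSum": 0.1,
    "ReadPosRankSum": -0.3,
}


def make_call(
    chrom="1",
    pos=1000,
    ref="A",
    alt="G",
    qual=100.0,
    genotype=None,
    rsid=None,
    **annotation_overrides,
):
    """A comfortably passing call unless annotations are overridden.

    An override of None removes the annotation entirely (missing)."""
    annotations = dict(GOOD_ANNOTATIONS)
    for key, value in annotation_overrides.items():
        if value is None:
            annotations.pop(key, None)
        else:
            annotations[key] = value
    key = VariantKey(chrom, pos, ref, alt)
    return VariantCall(
        key=key,
        qual=qual,
        genotype=genotype or (ref, alt),
        annotations=annotations,
        rsid=rsid,
    )


def make_callset(sample_id, group, sex, calls):
    return SampleCallset(sample_id, group, sex, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20151209)


@pytest.fixture
def toy_cohort():
    """Five-variant toy cohort: one case with three passing SNVs, one control
    with two passing SNVs (hand-enumerable)."""
    case = make_callset(
        "A1", "case", "M",
        [make_call(pos=p) for p in (100, 200, 300)],
    )
    control = make_callset(
        "C1", "control", "M",
        [make_call(pos=p) for p in (400, 500)],
    )
    return CohortStudy(cases=[case], controls=[control])
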