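import pytest
from hypothesis import HealthCheck, settings

from septcall.qpcr_data import (
    Group,
    ReplicateMeasurement,
    SampleRecord,
    Specimen,
    Stage,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


def make_sample(
    sept9_cps,
    actb_cps=None,
    *,
    specimen=Specimen.STOOL,
    group=Group.CRC,
    stage=Stage.II,
    sample_id="smp-1",
    subject_id=None,
    **covariates,
):
    """Build a SampleRecord from Cp tuples (None = non-detected)."""
    if actb_cps is None:
        actb_cps = [30.0] * len(sept9_cps)
    if group is not Group.CRC:
        stage = Stage.NOT_APPLICABLE
    return SampleRecord(
        sample_id=sample_id,
        subject_id=subject_id or sample_id,
        specimen=specimen,
        group=group,
        stage=stage,
        replicates=tuple(
            ReplicateMeasurement(actb_cp=a, sept9_cp=s)
            for a, s in zip(actb_cps, sept9_cps)
        ),
        **covariates,
    )


@pytest.fixture
def sample_factory():
    return make_sample
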