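import numpy as np
import pytest

from ckdval import Cohort, PatientRecord, SimulationConfig, generate_cohort


def make_record(**kw) -> PatientRecord:
    """A valid baseline record; override any field via kwargs."""
    base = dict(
        id="p1", age=76.0, sex="male", race_black=False, cvd_history=False,
        diabetes=False, smoker=False, sbp=143.0, egfr=18.0, acr=391.0,
        censor_time=5.0,
    )
    base.update(kw)
    if "death_time" in kw and "censor_time" not in kw:
        base.pop("censor_time")
    return PatientRecord(**base)


@pytest.fixture(scope="session")
def small_synthetic():
    """A 400-subject default-process cohort with 2-year oracle risks."""
    cfg = SimulationConfig(n=400, seed=20240917)
    cohort, oracle = generate_cohort(cfg, with_oracle=True, oracle_horizons=(2.0,))
    return cohort, oracle[2.0]


@pytest.fixture
def rng():
    return np.random.default_rng(1729)
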