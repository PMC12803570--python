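import numpy as np
import pytest

from t2dsim.cohort import Participant, PriorEventHistory, RiskFactorVector
from t2dsim.equations import CoefficientSet, EquationSpec, illustrative_coefficients

COMPLETE_BASELINE = dict(
    weight=86.0,
    hdl=1.1,
    ldl=2.3,
    sbp=135.0,
    hba1c=7.3,
    heart_rate=72.0,
    wbc=7.5,
    haemoglobin=13.8,
    egfr=75.0,
    smoking=False,
    af=False,
    pad=False,
    albuminuria=False,
)


def make_participant(pid="p1", arm="active", age=65.0, sex="male", prior=(), **baseline_overrides):
    """A participant with a complete, in-range baseline unless overridden."""
    base = dict(COMPLETE_BASELINE)
    base.update(baseline_overrides)
    return Participant(
        id=pid,
        arm=arm,
        age=age,
        sex=sex,
        diabetes_duration=10.0,
        height=170.0,
        baseline=RiskFactorVector(**base),
        prior=PriorEventHistory.from_flags(prior),
    )


@pytest.fixture
def participant_factory():
    return make_participant


@pytest.fixture(scope="session")
def eqs():
    return illustrative_coefficients()


def constant_hazard_set(rate: float, name: str = "death", kind: str = "death") -> CoefficientSet:
    """A one-equation coefficient set with a covariate-free constant hazard."""
    return CoefficientSet(
        version="test-constant",
        equations=[
            EquationSpec(name=name, kind=kind, intercept=float(np.log(rate)), coefficients={})
        ],
    )


@pytest.fixture
def constant_hazard():
    return constant_hazard_set
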