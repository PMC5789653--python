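import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from eqpoint.feedback_core import (
    STIMULATORY,
    SUPPRESSIVE,
    EffectorCurve,
    FeedbackSystem,
    SensorCurve,
    predefined_system,
)


@pytest.fixture
def calcium_system() -> FeedbackSystem:
    return predefined_system("calcium_pth")


@pytest.fixture
def glucose_system() -> FeedbackSystem:
    return predefined_system("glucose_insulin")


def random_valid_system(rng: np.random.Generator) -> FeedbackSystem:
    """A random negative-feedback loop with parameters in a sane band."""
    if rng.random() < 0.5:
        sdir, edir = SUPPRESSIVE, STIMULATORY
    else:
        sdir, edir = STIMULATORY, SUPPRESSIVE
    return FeedbackSystem(
        name="random",
        sensor=SensorCurve(
            direction=sdir,
            alpha=float(rng.uniform(-2.0, 2.0)),
            beta=float(rng.uniform(0.2, 2.0)),
        ),
        effector=EffectorCurve(
            direction=edir,
            p0=float(rng.uniform(0.1, 1.0)),
            gain=float(rng.uniform(0.5, 3.0)),
            k=float(rng.uniform(0.2, 3.0)),
        ),
    )
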