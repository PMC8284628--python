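import numpy as np
import pytest

from saccade_adapt import (
    REFERENCE_MODEL1, REFERENCE_MODEL2,
    build_exp1_schedule, build_exp2_schedule,
)
from saccade_adapt.schedules import Exp1Config, Exp2Config


@pytest.fixture(scope="session")
def exp1():
    return build_exp1_schedule()


@pytest.fixture(scope="session")
def exp2():
    return build_exp2_schedule()


@pytest.fixture(scope="session")
def mini_exp2():
    """Short adaptation/extinction/clamp schedule for fitting-heavy tests.

    Keeps the structural features that identify the models (a mid-adaptation
    set break, a sign switch, the pre-clamp break, an error-clamp block) at
    a fraction of the full trial count.
    """
    return build_exp2_schedule(Exp2Config(
        n_baseline=8, n_adaptation=120, n_extinction=24, n_clamp=40,
        adaptation_breaks=(60,),
    ))


@pytest.fixture(scope="session")
def mini_exp1():
    """Short alternating perturbation/error-clamp schedule with set breaks.

    The many set breaks carry the signal that discriminates the coupled
    (model 1) from the decoupled (model 2) break-decay structure, making
    this the design of choice for scaled-down model-recovery runs.
    """
    return build_exp1_schedule(Exp1Config(
        n_baseline=8, first_adaptation=40, final_clamp=40, period_length=24,
        n_adaptation_periods=4, n_clamp_periods=4, expected_total=None,
    ))


@pytest.fixture(scope="session")
def m1_ref():
    return REFERENCE_MODEL1


@pytest.fixture(scope="session")
def m2_ref():
    return REFERENCE_MODEL2
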