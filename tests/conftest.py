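import numpy as np
import pytest

from fluoroskill.cohort import (
    BehaviorProfile,
    CohortConfig,
    _angle_params,
    make_cohort,
)
from fluoroskill.kinematics import default_carm, default_phantom
from fluoroskill.protocol import VIEWS
from fluoroskill.scoring import fit_reference, score_records


@pytest.fixture(scope="session")
def phantom():
    return default_phantom()


@pytest.fixture(scope="session")
def carm():
    return default_carm()


def make_flat_profile(group="experienced", bias=0.0, tau=0.0, sigma=0.0, **kw):
    """Profile with identical (bias, tau, sigma) for every angle."""
    params = {
        (spec.view_id, angle): (bias, tau, sigma)
        for spec in VIEWS
        for angle in spec.angle_names
    }
    return BehaviorProfile(group=group, angle_params=params, **kw)


@pytest.fixture(scope="session")
def study_cohort():
    """Default-preset cohort at the study's group sizes (11 vs 9)."""
    return make_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def study_scores(study_cohort):
    ref = fit_reference(study_cohort)
    return score_records(study_cohort, ref)
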