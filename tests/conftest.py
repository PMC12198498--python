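import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import diffgek as dg
from diffgek import FitConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_fit_config():
    """Reduced multi-start budget for unit tests of the fit machinery."""
    return FitConfig(n_starts=60, n_polish=5, n_final=2, maxiter=400)


def make_flat_course(alpha=2.0, beta=1.0, gamma=0.5, u0=0.4, s0=0.3, condition="c0"):
    """Noise-free pooled course generated from constant rates."""
    t = dg.default_simulation_times()
    kin = dg.KineticParams(
        dg.RateSpline.constant(alpha),
        dg.RateSpline.constant(beta),
        dg.RateSpline.constant(gamma),
        u0,
        s0,
    )
    traj = dg.integrate_kinetics(kin, t)
    return dg.GeneTimeCourse(t, traj.u, traj.s, condition=condition), kin


@pytest.fixture
def flat_course():
    course, _ = make_flat_course()
    return course
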