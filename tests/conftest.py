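import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from skillfit.ddm import ContaminantSpec, DDMParams, QuadratureConfig
from skillfit.learning_curve import CurveParams
from skillfit.optim import OptimizerConfig
from skillfit.synthetic import make_design, simulate_curve_rts, simulate_ddm_trials

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: moderate optimizer effort for tests: adequate for the small fitting
#: problems exercised here while keeping the suite fast
FAST_CURVE_OPT = OptimizerConfig(swarm_size=20, iterations=80, n_restarts=1)
FAST_DDM_OPT = OptimizerConfig(
    swarm_size=12,
    iterations=50,
    n_restarts=1,
    polish_maxfev_per_dim=25,
    stall_iterations=10,
)
FIT_QUAD = QuadratureConfig(n_drift=7, n_start=3, n_t0=5)

TRUE_CURVE = CurveParams(RT0=0.55, B=0.45, alpha=0.12)
TRUE_DDM = DDMParams(v=5.0, a=1.2, t0=0.33, sv=1.5, sz=0.3, st0=0.1)


@pytest.fixture
def fast_curve_opt():
    return FAST_CURVE_OPT


@pytest.fixture
def fast_ddm_opt():
    return FAST_DDM_OPT


@pytest.fixture
def fit_quad():
    return FIT_QUAD


@pytest.fixture(scope="session")
def exp1_skeleton():
    _, skel = make_design(1, 8, seed=123)
    return skel


@pytest.fixture(scope="session")
def curve_trials(exp1_skeleton):
    """One participant's session with identical curve truth in both conditions."""
    return simulate_curve_rts(exp1_skeleton, TRUE_CURVE, 0.15, seed=7)


def make_ddm_condition_data(
    n_per_condition=160,
    params_f=TRUE_DDM,
    params_if=None,
    seed=0,
    contaminant=ContaminantSpec(proportion=0.05),
    dt=1e-4,
):
    """Two-condition asymptotic trials from (possibly different) DDM truths."""
    params_if = params_if or params_f
    rng = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    frames = []
    for cond, params, s in (("F", params_f, rng[0]), ("I+F", params_if, rng[1])):
        df = simulate_ddm_trials(n_per_condition, params, contaminant, seed=int(s), dt=dt)
        df["instruction"] = cond
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
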