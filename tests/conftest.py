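import numpy as np
import pytest

import aclfjm as a
from aclfjm.joint import JointModelFit, JointParams, JointSpec
from aclfjm.lmm import LongitudinalSpec


@pytest.fixture(scope="session")
def small_cohort():
    """A 250-patient cohort under the parameter-recovery condition."""
    return a.simulate_cohort(a.recovery_config(n_patients=250, rng_seed=42))


@pytest.fixture(scope="session")
def small_spec():
    return JointSpec(longitudinal=LongitudinalSpec(),
                     survival_covariates=("female", "life_support"),
                     n_hazard_segments=3, gh_nodes=3)


@pytest.fixture(scope="session")
def small_fit(small_cohort, small_spec):
    """Joint fit on the small cohort, shared across downstream tests."""
    return a.fit_joint_model(small_cohort.baseline, small_cohort.longitudinal,
                             small_cohort.outcome, small_spec, compute_se=False)


def make_toy_fit(intercept=20.0, slope=0.0, alpha_value=0.14, alpha_slope=0.0,
                 lam=0.005, sigma=1.0, d_diag=(25.0, 0.0025),
                 gamma_names=(), gamma=()):
    """Hand-assembled joint fit: linear trajectory basis, constant baseline
    hazard, no longitudinal covariates.  Lets prediction tests control every
    parameter exactly."""
    spec = JointSpec(longitudinal=LongitudinalSpec(),
                     survival_covariates=tuple(gamma_names),
                     n_hazard_segments=1, gh_nodes=3)
    params = JointParams(
        beta=np.array([intercept, slope]), D=np.diag(d_diag), sigma=sigma,
        gamma=np.array(gamma, dtype=float), alpha_value=alpha_value,
        alpha_slope=alpha_slope, log_lambda=np.array([np.log(lam)]))
    return JointModelFit(
        spec=spec, params=params, beta_names=["intercept", "time1"],
        gamma_names=list(gamma_names), boundaries=np.array([0.0]),
        loglik=0.0, converged=True, n_iter=0, message="toy",
        basis_state={"kind": "linear"})


@pytest.fixture
def toy_fit_factory():
    return make_toy_fit
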