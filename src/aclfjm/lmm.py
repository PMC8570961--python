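"""Linear mixed-effects submodel for repeated MELD-Na.

Model: for patient i with measurements y_ij at times t_ij,

    y_ij = x_ij' beta + z_ij' b_i + eps_ij,   b_i ~ N(0, D),  eps ~ N(0, sigma^2)

with x the fixed design (intercept, time basis, optional baseline covariates)
and z the random design (intercept + time slope by default).  Estimation is
direct maximization of the closed-form marginal Gaussian likelihood with beta
profiled out by GLS, so fits are deterministic and fast at registry scale.
Patient-level curves come from the empirical-Bayes (BLUP) modes of b_i;
slopes use analytic basis derivatives.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .basis import TimeBasis, make_basis

_LOG_SIGMA_FLOOR = np.log(1e-6)


class RankDeficiencyError(ValueError):
    pass


class NonConvergenceError(RuntimeError):
    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class UnknownPatientError(KeyError):
    pass


@dataclass
class LongitudinalSpec:
    """Design of the mixed model.

    ``time_basis``: 'linear' or 'ns' (natural cubic spline; knots default to
    evenly spaced percentiles of the observation times).  ``random``:
    'intercept_slope' (default) or 'full' (random coefficients on every
    basis column).  ``covariates`` are baseline (time-fixed) columns taken
    from the baseline table.
    """

    time_basis: str = "linear"
    n_interior_knots: int = 2
    interior_knots: tuple | None = None
    boundary_knots: tuple | None = None
    covariates: tuple = ()
    random: str = "intercept_slope"
    value_col: str = "meld_na"

    def build_basis(self, times) -> TimeBasis:
        return make_basis(self.time_basis, times=times,
                          n_interior=self.n_interior_knots,
                          interior_knots=self.interior_knots,
                          boundary_knots=self.boundary_knots)


def design_names(spec: LongitudinalSpec, basis: TimeBasis):
    time_cols = [f"time{j+1}" for j in range(basis.n_cols)]
    return ["intercept"] + time_cols + list(spec.covariates)


def build_design(t, basis: TimeBasis, cov_row: np.ndarray, spec: LongitudinalSpec):
    """Fixed and random design rows at times ``t`` for one patient."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    B = basis.matrix(t)
    ones = np.ones((t.size, 1))
    cov = np.tile(cov_row, (t.size, 1)) if cov_row.size else np.empty((t.size, 0))
    X = np.hstack([ones, B, cov])
    Z = np.hstack([ones, B]) if spec.random == "full" else np.hstack([ones, B[:, :1]])
    return X, Z


def build_design_deriv(t, basis: TimeBasis, n_cov: int, spec: LongitudinalSpec):
    """d/dt of the fixed and random design rows (covariates are time-fixed)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    dB = basis.deriv(t)
    zeros = np.zeros((t.size, 1))
    dX = np.hstack([zeros, dB, np.zeros((t.size, n_cov))])
    dZ = np.hstack([zeros, dB]) if spec.random == "full" else np.hstack([zeros, dB[:, :1]])
    return dX, dZ


@dataclass
class LongitudinalFit:
    spec: LongitudinalSpec
    basis: TimeBasis
    beta: np.ndarray
    beta_names: list
    D: np.ndarray
    sigma: float
    ranef: pd.DataFrame  # EB modes, one row per patient
    loglik: float
    converged: bool
    n_iter: int
    message: str
    covariate_rows: dict = field(default_factory=dict)  # pid -> covariate vector
    posterior_cov: dict = field(default_factory=dict)  # pid -> 2x2 (or dxd)


# --- likelihood machinery ---------------------------------------------------

def gaussian_marginal_loglik(y_list, X_list, Z_list, beta, D, sigma):
    """Exact marginal log-likelihood of the LMM (random effects integrated
    out analytically): sum_i log N(y_i; X_i beta, Z_i D Z_i' + sigma^2 I)."""
    ll = 0.0
    for y, X, Z in zip(y_list, X_list, Z_list):
        V = Z @ D @ Z.T + sigma ** 2 * np.eye(len(y))
        L = np.linalg.cholesky(V)
        r = y - X @ beta
        u = np.linalg.solve(L, r)
        ll += -0.5 * (len(y) * np.log(2 * np.pi)) - np.log(np.diag(L)).sum() - 0.5 * u @ u
    return float(ll)


def _unpack_theta(theta, d):
    """theta -> (D, sigma) via a log-Cholesky parameterization."""
    L = np.zeros((d, d))
    idx = 0
    for i in range(d):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(theta[idx])
            else:
                L[i, j] = theta[idx]
            idx += 1
    sigma = float(np.exp(theta[idx]))
    return L @ L.T, sigma


def _pack_theta(D, sigma, d):
    L = np.linalg.cholesky(D + 1e-10 * np.eye(d))
    theta = []
    for i in range(d):
        for j in range(i + 1):
            theta.append(np.log(L[i, j]) if i == j else L[i, j])
    theta.append(np.log(sigma))
    return np.array(theta)


def _profile_beta(y_list, X_list, Z_list, D, sigma):
    """GLS beta given variance parameters, plus the profiled log-likelihood."""
    p = X_list[0].shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    chols, n_total = [], 0
    for y, X, Z in zip(y_list, X_list, Z_list):
        V = Z @ D @ Z.T + sigma ** 2 * np.eye(len(y))
        L = np.linalg.cholesky(V)
        Xi = np.linalg.solve(L, X)
        yi = np.linalg.solve(L, y)
        XtVX += Xi.T @ Xi
        XtVy += Xi.T @ yi
        chols.append((L, Xi, yi))
        n_total += len(y)
    beta = np.linalg.solve(XtVX, XtVy)
    ll = -0.5 * n_total * np.log(2 * np.pi)
    for L, Xi, yi in chols:
        u = yi - Xi @ beta
        ll += -np.log(np.diag(L)).sum() - 0.5 * u @ u
    return beta, float(ll)


def _prepare(longitudinal: pd.DataFrame, spec: LongitudinalSpec,
             baseline: pd.DataFrame | None):
    t_all = longitudinal["t"].to_numpy(dtype=float)
    if not np.all(np.isfinite(t_all)):
        raise ValueError("non-finite measurement times")
    basis = spec.build_basis(t_all)
    if spec.covariates:
        if baseline is None:
            raise ValueError("spec has covariates but no baseline table was given")
        cov_lookup = baseline.set_index("patient_id")[list(spec.covariates)]
    pids, y_list, X_list, Z_list, cov_rows = [], [], [], [], {}
    for pid, grp in longitudinal.groupby("patient_id", sort=True):
        if len(grp) < 1:
            continue
        cov_row = (cov_lookup.loc[pid].to_numpy(dtype=float)
                   if spec.covariates else np.empty(0))
        X, Z = build_design(grp["t"].to_numpy(), basis, cov_row, spec)
        pids.append(pid)
        y_list.append(grp[spec.value_col].to_numpy(dtype=float))
        X_list.append(X)
        Z_list.append(Z)
        cov_rows[pid] = cov_row
    names = design_names(spec, basis)
    Xs = np.vstack(X_list)
    rank = np.linalg.matrix_rank(Xs)
    if rank < Xs.shape[1]:
        for j in range(Xs.shape[1]):
            others = np.delete(Xs, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                raise RankDeficiencyError(
                    f"design column {names[j]!r} is collinear with the others")
        raise RankDeficiencyError("design matrix is rank deficient")
    return pids, y_list, X_list, Z_list, cov_rows, basis, names


def fit_lmm(longitudinal: pd.DataFrame, spec: LongitudinalSpec | None = None,
            baseline: pd.DataFrame | None = None) -> LongitudinalFit:
    """Maximum-likelihood fit of the mixed model; EB modes per patient.

    Raises :class:`RankDeficiencyError` for singular designs (naming the
    column) and :class:`NonConvergenceError` (carrying the optimizer trace)
    if the variance-parameter search fails.
    """
    spec = spec or LongitudinalSpec()
    pids, y_list, X_list, Z_list, cov_rows, basis, names = _prepare(
        longitudinal, spec, baseline)
    d = Z_list[0].shape[1]

    # moment-style init: OLS residual spread split between levels
    y_all = np.concatenate(y_list)
    sd0 = max(np.std(y_all), 1e-3)
    D0 = np.diag([sd0 ** 2 * 0.5] + [0.01] * (d - 1))
    theta0 = _pack_theta(D0, sd0 * 0.5, d)

    trace = []

    def negll(theta):
        D, sigma = _unpack_theta(theta, d)
        try:
            _, ll = _profile_beta(y_list, X_list, Z_list, D, sigma)
        except np.linalg.LinAlgError:
            return 1e12
        trace.append((theta.copy(), ll))
        return -ll

    bounds = [(None, None)] * (len(theta0) - 1) + [(_LOG_SIGMA_FLOOR, None)]
    res = optimize.minimize(negll, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    if not np.isfinite(res.fun):
        raise NonConvergenceError("variance-parameter search diverged", trace)
    D, sigma = _unpack_theta(res.x, d)
    beta, ll = _profile_beta(y_list, X_list, Z_list, D, sigma)

    ranef_rows, post_cov = [], {}
    Dinv = np.linalg.inv(D + 1e-12 * np.eye(d))
    for pid, y, X, Z in zip(pids, y_list, X_list, Z_list):
        V = Z @ D @ Z.T + sigma ** 2 * np.eye(len(y))
        b = D @ Z.T @ np.linalg.solve(V, y - X @ beta)
        ranef_rows.append(b)
        A = Z.T @ Z / sigma ** 2 + Dinv
        post_cov[pid] = np.linalg.inv(A)
    ranef = pd.DataFrame(ranef_rows, index=pd.Index(pids, name="patient_id"),
                         columns=[f"b{k}" for k in range(d)])

    return LongitudinalFit(
        spec=spec, basis=basis, beta=beta, beta_names=names, D=D, sigma=sigma,
        ranef=ranef, loglik=ll, converged=bool(res.success), n_iter=int(res.nit),
        message=str(res.message), covariate_rows=cov_rows, posterior_cov=post_cov)


def save_fit(fit: LongitudinalFit, path) -> None:
    """Persist a mixed-model fit as a versioned plain-text parameter file."""
    import json
    from pathlib import Path
    basis = fit.basis
    basis_state = ({"kind": "ns", "interior": list(basis.knots[1:-1]),
                    "boundary": [float(basis.knots[0]), float(basis.knots[-1])]}
                   if hasattr(basis, "knots") else {"kind": "linear"})
    payload = {
        "format": "aclfjm-lmm-fit/1",
        "spec": {"time_basis": fit.spec.time_basis,
                 "covariates": list(fit.spec.covariates),
                 "random": fit.spec.random, "value_col": fit.spec.value_col},
        "basis_state": basis_state,
        "beta": fit.beta.tolist(), "beta_names": fit.beta_names,
        "D": fit.D.tolist(), "sigma": fit.sigma, "loglik": fit.loglik,
        "converged": fit.converged,
        "ranef": {str(pid): row.tolist()
                  for pid, row in fit.ranef.iterrows()},
        "covariate_rows": {str(pid): np.asarray(v).tolist()
                           for pid, v in fit.covariate_rows.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_fit(path) -> LongitudinalFit:
    """Load a fit written by :func:`save_fit`."""
    import json
    from pathlib import Path
    obj = json.loads(Path(path).read_text())
    if obj.get("format") != "aclfjm-lmm-fit/1":
        raise ValueError("not a mixed-model fit artifact")
    sp = obj["spec"]
    spec = LongitudinalSpec(time_basis=sp["time_basis"],
                            covariates=tuple(sp["covariates"]),
                            random=sp["random"], value_col=sp["value_col"])
    bs = obj["basis_state"]
    basis = make_basis(bs["kind"], interior_knots=bs.get("interior"),
                       boundary_knots=bs.get("boundary"))
    ranef = pd.DataFrame.from_dict(obj["ranef"], orient="index")
    ranef.index.name = "patient_id"
    ranef.columns = [f"b{k}" for k in range(ranef.shape[1])]
    return LongitudinalFit(
        spec=spec, basis=basis, beta=np.array(obj["beta"]),
        beta_names=obj["beta_names"], D=np.array(obj["D"]),
        sigma=obj["sigma"], ranef=ranef, loglik=obj["loglik"],
        converged=obj["converged"], n_iter=0, message="loaded",
        covariate_rows={pid: np.array(v)
                        for pid, v in obj["covariate_rows"].items()})


def trajectory(fit: LongitudinalFit, patient_id, t):
    """Patient-specific fitted value m_i(t) and analytic slope m_i'(t)."""
    if patient_id not in fit.ranef.index:
        raise UnknownPatientError(f"no fitted random effects for {patient_id!r}")
    b = fit.ranef.loc[patient_id].to_numpy()
    cov_row = fit.covariate_rows.get(patient_id, np.empty(0))
    X, Z = build_design(t, fit.basis, cov_row, fit.spec)
    dX, dZ = build_design_deriv(t, fit.basis, cov_row.size, fit.spec)
    value = X @ fit.beta + Z @ b
    slope = dX @ fit.beta + dZ @ b
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(value[0]), float(slope[0])
    return value, slope
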