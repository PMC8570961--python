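"""Dynamic, patient-specific survival prediction.

Given a fitted joint model and one patient's baseline covariates plus the
MELD-Na measurements observed up to a landmark time t, computes the
conditional survival curve

    pi_i(u | t) = E[ S_i(u | b) / S_i(t | b)  |  history up to t ]

where the expectation runs over the posterior of the patient's random
effects given the history (measurements and survival to t).  Two modes:

* ``mc`` (default) - importance sampling centred at the empirical-Bayes
  posterior with a multivariate-t proposal (df=4), fully seedable;
* ``plugin`` - first-order plug-in at the EB mode, essentially free, used
  for cohort-scale ranking and validation.

Predictions update with every new measurement: appending a high MELD-Na
point steepens the fitted slope and pushes the whole curve down.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss

from .joint import JointModelFit, SchemaError
from .lmm import build_design, build_design_deriv


class PredictionError(ValueError):
    pass


@dataclass
class DynamicPrediction:
    patient_id: str
    t: float
    u_grid: np.ndarray
    pi: np.ndarray
    band_lo: np.ndarray | None
    band_hi: np.ndarray | None
    n_draws: int
    seed: int | None
    method: str

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"u": self.u_grid, "pi": self.pi})
        if self.band_lo is not None:
            df["lo"] = self.band_lo
            df["hi"] = self.band_hi
        df.insert(0, "patient_id", self.patient_id)
        df.insert(1, "t", self.t)
        return df


# --- cumulative-hazard machinery -------------------------------------------

class _HazardIntegrator:
    """Gauss-Legendre integration of exp(alpha_v m + alpha_s m') over the
    piecewise-constant baseline-hazard segments of a fit.

    The last segment's hazard extends beyond the final boundary, so curves
    extrapolate past the training follow-up.
    """

    def __init__(self, fit: JointModelFit, gl_nodes: int | None = None):
        self.fit = fit
        self.basis = fit.make_basis()
        self.bnd = np.asarray(fit.boundaries, dtype=float)
        self.lam = np.exp(fit.params.log_lambda)
        self.xi, self.om = leggauss(gl_nodes or fit.spec.gl_nodes)

    def _segments(self, t0: float, t1: float):
        """(a_k, b_k, lambda_k) for the overlap of each segment with [t0, t1]."""
        bnd = self.bnd
        out = []
        for k in range(len(bnd)):
            a = max(bnd[k], t0)
            b = min(bnd[k + 1], t1) if k < len(bnd) - 1 else t1
            if b > a:
                out.append((a, b, self.lam[k]))
        return out

    def quad_points(self, t0: float, t1: float):
        """Times, GL-weight*lambda products for integrating over [t0, t1]."""
        times, wts = [], []
        for a, b, lam in self._segments(t0, t1):
            times.append((a + b) / 2.0 + (b - a) / 2.0 * self.xi)
            wts.append((b - a) / 2.0 * self.om * lam)
        if not times:
            return np.empty(0), np.empty(0)
        return np.concatenate(times), np.concatenate(wts)

    def cumhaz(self, cov_row: np.ndarray, lin_w: float, B: np.ndarray,
               t0: float, t1: float) -> np.ndarray:
        """Integral of h over [t0, t1] for each random-effect draw in B (J,d)."""
        s, w = self.quad_points(t0, t1)
        if s.size == 0:
            return np.zeros(len(B))
        lspec = self.fit.spec.longitudinal
        X, Z = build_design(s, self.basis, cov_row, lspec)
        dX, dZ = build_design_deriv(s, self.basis, cov_row.size, lspec)
        p = self.fit.params
        m = X @ p.beta + B @ Z.T  # (J, G)
        assoc = p.alpha_value * m
        if p.alpha_slope != 0.0:
            assoc = assoc + p.alpha_slope * (dX @ p.beta + B @ dZ.T)
        return np.exp(lin_w) * np.exp(np.clip(assoc, -700, 700)) @ w


def _patient_vectors(fit: JointModelFit, baseline_row) -> tuple[np.ndarray, float]:
    lspec = fit.spec.longitudinal
    row = baseline_row if isinstance(baseline_row, dict) else dict(baseline_row)
    missing = [c for c in (*fit.gamma_names, *lspec.covariates) if c not in row]
    if missing:
        raise SchemaError(f"baseline record lacks covariates: {missing}")
    cov_row = np.array([float(row[c]) for c in lspec.covariates])
    w = np.array([float(row[c]) for c in fit.gamma_names])
    return cov_row, float(w @ fit.params.gamma)


def _posterior_moments(fit: JointModelFit, cov_row, t_obs, y_obs):
    """Gaussian posterior of b given the longitudinal history alone."""
    lspec = fit.spec.longitudinal
    basis = fit.make_basis()
    X, Z = build_design(t_obs, basis, cov_row, lspec)
    p = fit.params
    d = p.D.shape[0]
    Dinv = np.linalg.inv(p.D)
    A = Z.T @ Z / p.sigma ** 2 + Dinv
    Sig = np.linalg.inv(A)
    r = y_obs - X @ p.beta
    mu = Sig @ (Z.T @ r) / p.sigma ** 2
    # pieces for importance weights
    def log_joint(B):
        resid = r[None, :] - B @ Z.T
        ll = -0.5 * (resid ** 2).sum(axis=1) / p.sigma ** 2
        lp = -0.5 * np.einsum("jd,de,je->j", B, Dinv, B)
        return ll + lp
    return mu, Sig, log_joint, d


def predict_survival(fit: JointModelFit, baseline_row, measurements: pd.DataFrame,
                     t: float, u_grid, n_draws: int = 200, seed: int | None = 0,
                     method: str = "mc") -> DynamicPrediction:
    """Conditional survival curve pi(u|t) for one patient.

    ``measurements`` needs columns ``t`` and the longitudinal value column;
    rows after the landmark are ignored.  ``u_grid`` must lie at or beyond
    ``t``; pi(t|t) is exactly 1.
    """
    lspec = fit.spec.longitudinal
    val_col = lspec.value_col if lspec.value_col in measurements.columns else "meld_na"
    hist = measurements[measurements["t"] <= t + 1e-12]
    if len(hist) == 0:
        if len(measurements):
            raise PredictionError(
                f"landmark t={t} precedes the first measurement "
                f"(t={measurements['t'].min()})")
        raise PredictionError("history is empty: at least one measurement is required")
    u_grid = np.atleast_1d(np.asarray(u_grid, dtype=float))
    if np.any(u_grid < t):
        raise PredictionError("prediction grid must satisfy u >= t")

    cov_row, lin_w = _patient_vectors(fit, baseline_row)
    mu, Sig, log_joint, d = _posterior_moments(
        fit, cov_row, hist["t"].to_numpy(dtype=float),
        hist[val_col].to_numpy(dtype=float))
    integ = _HazardIntegrator(fit)

    if method == "plugin":
        B = mu[None, :]
        logw = np.zeros(1)
        n_used = 1
    elif method == "mc":
        rng = np.random.default_rng(seed)
        df_t = 4.0
        L = np.linalg.cholesky(Sig + 1e-12 * np.eye(d))
        z = rng.standard_normal((n_draws, d))
        g = rng.chisquare(df_t, n_draws) / df_t
        B = mu[None, :] + (z @ L.T) / np.sqrt(g)[:, None]
        # multivariate-t proposal log-density (constants cancel in the ratio)
        delta = B - mu[None, :]
        sol = np.linalg.solve(Sig, delta.T).T
        quad = np.einsum("jd,jd->j", delta, sol)
        logq = -0.5 * (df_t + d) * np.log1p(quad / df_t)
        logw = log_joint(B) - logq
        logw -= logw.max()
        n_used = n_draws
    else:
        raise ValueError(f"unknown method {method!r}")

    w = np.exp(logw)
    H_t = integ.cumhaz(cov_row, lin_w, B, 0.0, t) if t > 0 else np.zeros(len(B))
    S_t = np.exp(-H_t)
    pi = np.empty(u_grid.size)
    ratios = np.empty((u_grid.size, len(B)))
    for k, u in enumerate(u_grid):
        H_u = H_t + integ.cumhaz(cov_row, lin_w, B, t, float(u))
        S_u = np.exp(-H_u)
        pi[k] = float(np.sum(w * S_u) / np.sum(w * S_t))
        ratios[k] = S_u / np.maximum(S_t, 1e-300)

    band_lo = band_hi = None
    if method == "mc":
        wpost = w * S_t
        wpost = wpost / wpost.sum()
        band_lo = np.empty(u_grid.size)
        band_hi = np.empty(u_grid.size)
        for k in range(u_grid.size):
            lo, hi = _weighted_quantiles(ratios[k], wpost, (0.025, 0.975))
            band_lo[k] = min(lo, pi[k])
            band_hi[k] = max(hi, pi[k])
    return DynamicPrediction(
        patient_id=str(baseline_row.get("patient_id", "?")
                       if hasattr(baseline_row, "get") else "?"),
        t=float(t), u_grid=u_grid, pi=pi, band_lo=band_lo, band_hi=band_hi,
        n_draws=n_used, seed=seed, method=method)


def _weighted_quantiles(x, w, qs):
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cum = np.cumsum(ws) - 0.5 * ws
    return tuple(float(np.interp(q, cum, xs)) for q in qs)


# --- cohort-scale plug-in predictor -----------------------------------------

class PlugInPredictor:
    """Vectorized EB plug-in predictions for a whole cohort.

    Precomputes, per patient, the running empirical-Bayes posterior mode
    after each successive measurement, so the risk of every active candidate
    can be refreshed cheaply at arbitrary landmark times (as the allocation
    experiment and the landmarked validation grid require).
    """

    def __init__(self, fit: JointModelFit, baseline: pd.DataFrame,
                 longitudinal: pd.DataFrame):
        self.fit = fit
        lspec = fit.spec.longitudinal
        self.basis = fit.make_basis()
        p = fit.params
        self.Dinv = np.linalg.inv(p.D)
        base = baseline.set_index("patient_id")
        self.pids = [pid for pid in base.index
                     if pid in set(longitudinal["patient_id"])]
        self._index = pd.Index(self.pids)
        n = len(self.pids)
        self.W = (base.loc[self.pids, list(fit.gamma_names)].to_numpy(dtype=float)
                  if fit.gamma_names else np.zeros((n, 0)))
        self.lin_w = self.W @ p.gamma if fit.gamma_names else np.zeros(n)
        self.cov = (base.loc[self.pids, list(lspec.covariates)].to_numpy(dtype=float)
                    if lspec.covariates else np.zeros((n, 0)))
        self.cov_beta = (self.cov @ p.beta[-len(lspec.covariates):]
                         if lspec.covariates else np.zeros(n))
        d = p.D.shape[0]
        self.d = d
        groups = dict(tuple(longitudinal.groupby("patient_id")))
        self.obs_times = []
        self.modes = []  # (n_obs, d) EB mode after each successive measurement
        self.values = []
        val_col = lspec.value_col
        for i, pid in enumerate(self.pids):
            g = groups[pid].sort_values("t")
            t = g["t"].to_numpy(dtype=float)
            y = g[val_col].to_numpy(dtype=float)
            X, Z = build_design(t, self.basis, self.cov[i], lspec)
            r = y - X @ p.beta
            A = self.Dinv.copy()
            c = np.zeros(d)
            modes = np.zeros((len(t), d))
            for j in range(len(t)):
                A = A + np.outer(Z[j], Z[j]) / p.sigma ** 2
                c = c + Z[j] * r[j] / p.sigma ** 2
                modes[j] = np.linalg.solve(A, c)
            self.obs_times.append(t)
            self.modes.append(modes)
            self.values.append(y)
        self.integ = _HazardIntegrator(fit)

    def eb_modes_at(self, t: float) -> np.ndarray:
        """EB mode per patient using measurements observed up to time t."""
        return self.modes_matrix(np.array([t]))[:, 0, :]

    def modes_matrix(self, times) -> np.ndarray:
        """EB modes per patient at several landmark times, shape (n, len(times), d).

        A patient's mode changes only when a new measurement arrives, so this
        is a cheap gather; patients with no measurement before a landmark use
        their first measurement's mode.
        """
        times = np.asarray(times, dtype=float)
        out = np.zeros((len(self.pids), times.size, self.d))
        for i, (t_obs, modes) in enumerate(zip(self.obs_times, self.modes)):
            idx = np.searchsorted(t_obs, times + 1e-12) - 1
            out[i] = modes[np.maximum(idx, 0)]
        return out

    def value_slope_at(self, t: float):
        """Fitted trajectory value and slope per patient at time t."""
        B = self.eb_modes_at(t)
        lspec = self.fit.spec.longitudinal
        p = self.fit.params
        X, Z = build_design([t], self.basis, np.empty(0),
                            _no_cov(lspec))
        dX, dZ = build_design_deriv([t], self.basis, 0, lspec)
        tpart = X[0] @ p.beta[:X.shape[1]]
        value = tpart + self.cov_beta + B @ Z[0]
        slope = dX[0] @ p.beta[:dX.shape[1]] + B @ dZ[0]
        return value, slope

    def _survival_from_modes(self, B: np.ndarray, t: float,
                             horizon: float) -> np.ndarray:
        s, wq = self.integ.quad_points(t, t + horizon)
        lspec = self.fit.spec.longitudinal
        p = self.fit.params
        if s.size == 0:
            return np.ones(len(self.pids))
        X, Z = build_design(s, self.basis, np.empty(0), _no_cov(lspec))
        dX, dZ = build_design_deriv(s, self.basis, 0, lspec)
        n_time = X.shape[1]
        tpart = X @ p.beta[:n_time]                      # (G,)
        m = tpart[None, :] + self.cov_beta[:, None] + B @ Z.T
        assoc = p.alpha_value * m
        if p.alpha_slope != 0.0:
            dm = (dX @ p.beta[:n_time])[None, :] + B @ dZ.T
            assoc = assoc + p.alpha_slope * dm
        H = np.exp(self.lin_w) * (np.exp(np.clip(assoc, -700, 700)) @ wq)
        return np.exp(-H)

    def survival(self, t: float, horizon: float) -> pd.Series:
        """Plug-in pi_i(t+horizon | t) for every patient, indexed by id."""
        return pd.Series(self._survival_from_modes(self.eb_modes_at(t), t, horizon),
                         index=self._index)

    def survival_matrix(self, times, horizon: float) -> np.ndarray:
        """pi_i(tau+horizon | tau) for every patient at every landmark tau,
        shape (n, len(times)); the workhorse of the allocation experiment."""
        times = np.asarray(times, dtype=float)
        modes = self.modes_matrix(times)
        out = np.empty((len(self.pids), times.size))
        for k, tau in enumerate(times):
            out[:, k] = self._survival_from_modes(modes[:, k, :], float(tau),
                                                  horizon)
        return out

    def last_value_matrix(self, times) -> np.ndarray:
        """Latest observed longitudinal value per patient at each time."""
        times = np.asarray(times, dtype=float)
        val_col = self.fit.spec.longitudinal.value_col
        out = np.empty((len(self.pids), times.size))
        for i, t_obs in enumerate(self.obs_times):
            idx = np.maximum(np.searchsorted(t_obs, times + 1e-12) - 1, 0)
            out[i] = self.values[i][idx]
        return out


def _no_cov(lspec):
    from dataclasses import replace
    return replace(lspec, covariates=())


def rank_by_mortality(fit: JointModelFit, baseline: pd.DataFrame,
                      longitudinal: pd.DataFrame, t: float,
                      horizon: float) -> list:
    """Patients ordered from most to least ill at landmark t.

    Orders by ascending predicted survival pi(t+horizon | t); ties break by
    longer waiting time (earlier listing) then lexicographic id, so the
    ranking is deterministic.
    """
    if len(baseline) == 0:
        return []
    pred = PlugInPredictor(fit, baseline, longitudinal)
    pi = pred.survival(t, horizon)
    listing = baseline.set_index("patient_id").get("listing_day")
    wait = (pd.Series(0.0, index=pi.index) if listing is None
            else t - listing.reindex(pi.index).fillna(0.0))
    df = pd.DataFrame({"pid": pi.index.to_numpy(), "pi": pi.to_numpy(),
                       "wait": wait.to_numpy()})
    df = df.sort_values(["pi", "wait", "pid"], ascending=[True, False, True],
                        kind="mergesort")
    return list(df["pid"])
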