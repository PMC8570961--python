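"""Joint longitudinal-survival model for waitlist mortality.

Couples the mixed-effects MELD-Na submodel to a proportional-hazards death
submodel through the *current* trajectory value and slope:

    h_i(t) = h0(t) * exp( gamma'w_i + alpha_value * m_i(t) + alpha_slope * m_i'(t) )

where m_i(t) = x_i(t)'beta + z_i(t)'b_i is the patient-specific mean
trajectory and w_i the baseline survival covariates (age, sex, cirrhosis,
ACLF-grade indicators, SBP, life support).  The baseline hazard h0 is
piecewise constant on segments cut at event-time quantiles.  The marginal
likelihood integrates the shared random effects b_i by adaptive
Gauss-Hermite quadrature centred at each patient's longitudinal posterior;
cumulative hazards use Gauss-Legendre quadrature on each hazard segment.

All ten published hazard-ratio multipliers of the fitted registry model are
shipped as an immutable fixture (:data:`PUBLISHED_FIT`) for worked examples
and the demo predictor; they are never used as fitting targets.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from numpy.polynomial.legendre import leggauss
from scipy import optimize

from .basis import make_basis
from .lmm import (LongitudinalSpec, LongitudinalFit, fit_lmm, build_design,
                  build_design_deriv, design_names, NonConvergenceError)


class SchemaError(ValueError):
    pass


class DegenerateDataError(ValueError):
    pass


class NumericalError(RuntimeError):
    pass


# --- published coefficients (worked-example fixture) ------------------------

@dataclass(frozen=True)
class PublishedCoefficients:
    """Per-term hazard-ratio multipliers of the registry-fitted model.

    Immutable; used for worked examples and the demo predictor only.  The
    slope multiplier is stored unit-agnostically (the source does not state
    the slope's time unit) and the age multiplier verbatim.
    """

    value: float = 1.15
    slope: float = 1.02
    age: float = 1.38
    female: float = 0.75
    cirrhosis: float = 0.95
    aclf1: float = 1.06
    aclf2: float = 1.98
    aclf3: float = 5.90
    sbp: float = 1.18
    life_support: float = 1.35

    def multipliers(self) -> dict:
        return dict(asdict(self))


PUBLISHED_FIT = PublishedCoefficients()


def hazard_ratio(model, patient: dict, reference: dict | None = None) -> float:
    """Relative hazard of two covariate/value/slope profiles.

    ``model`` is either a :class:`PublishedCoefficients` fixture or a
    :class:`JointModelFit`.  ``patient`` maps term names to values; terms not
    mentioned sit at the reference (all-zero) level.  The model is log-linear,
    so the result is the product of per-term multipliers raised to the
    covariate differences.
    """
    if isinstance(model, PublishedCoefficients):
        mult = model.multipliers()
    elif isinstance(model, JointModelFit):
        mult = model.hazard_ratios()
    else:
        raise SchemaError(f"cannot compute hazard ratios from {type(model).__name__}")
    reference = reference or {}
    for key in list(patient) + list(reference):
        if key not in mult:
            raise SchemaError(f"unknown covariate {key!r}; known terms: {sorted(mult)}")
    hr = 1.0
    for name, m in mult.items():
        diff = float(patient.get(name, 0.0)) - float(reference.get(name, 0.0))
        if diff != 0.0:
            hr *= m ** diff
    return hr


# --- model specification ----------------------------------------------------

DEFAULT_SURVIVAL_COVARIATES = ("age_c", "female", "cirrhosis",
                               "aclf1", "aclf2", "aclf3", "sbp", "life_support")


@dataclass
class JointSpec:
    """Structure of the joint model.

    ``gh_nodes`` is per random-effect dimension (3 -> 9 total points in the
    default 2-D random-effects space).  ``use_value``/``use_slope`` switch
    the association terms; both on by default.
    """

    longitudinal: LongitudinalSpec = field(default_factory=LongitudinalSpec)
    survival_covariates: tuple = DEFAULT_SURVIVAL_COVARIATES
    n_hazard_segments: int = 7
    gh_nodes: int = 3
    gl_nodes: int = 5
    use_value: bool = True
    use_slope: bool = True


@dataclass
class JointParams:
    """One point in parameter space (natural scale)."""

    beta: np.ndarray
    D: np.ndarray
    sigma: float
    gamma: np.ndarray
    alpha_value: float
    alpha_slope: float
    log_lambda: np.ndarray


def pack_params(p: JointParams, spec: JointSpec) -> np.ndarray:
    d = p.D.shape[0]
    L = np.linalg.cholesky(p.D + 1e-10 * np.eye(d))
    chol = []
    for i in range(d):
        for j in range(i + 1):
            chol.append(np.log(L[i, j]) if i == j else L[i, j])
    vec = list(p.beta) + chol + [np.log(p.sigma)] + list(p.gamma)
    if spec.use_value:
        vec.append(p.alpha_value)
    if spec.use_slope:
        vec.append(p.alpha_slope)
    vec += list(p.log_lambda)
    return np.array(vec, dtype=float)


def unpack_params(vec: np.ndarray, dims: dict, spec: JointSpec) -> JointParams:
    p, d, q, K = dims["p"], dims["d"], dims["q"], dims["K"]
    i = 0
    beta = vec[i:i + p]; i += p
    L = np.zeros((d, d))
    for r in range(d):
        for c in range(r + 1):
            L[r, c] = np.exp(vec[i]) if r == c else vec[i]
            i += 1
    sigma = float(np.exp(vec[i])); i += 1
    gamma = vec[i:i + q]; i += q
    alpha_value = float(vec[i]) if spec.use_value else 0.0
    i += int(spec.use_value)
    alpha_slope = float(vec[i]) if spec.use_slope else 0.0
    i += int(spec.use_slope)
    log_lambda = vec[i:i + K]
    return JointParams(beta=beta, D=L @ L.T, sigma=sigma, gamma=gamma,
                       alpha_value=alpha_value, alpha_slope=alpha_slope,
                       log_lambda=np.asarray(log_lambda, dtype=float))


# --- prepared data ----------------------------------------------------------

class JointData:
    """Padded, quadrature-ready arrays for the vectorized likelihood."""

    def __init__(self, baseline: pd.DataFrame, longitudinal: pd.DataFrame,
                 outcome: pd.DataFrame, spec: JointSpec):
        lspec = spec.longitudinal
        for col in ("patient_id", "t", lspec.value_col):
            if col not in longitudinal.columns:
                raise SchemaError(f"longitudinal table lacks column {col!r}")
        for col in ("patient_id", "event_time", "event_type"):
            if col not in outcome.columns:
                raise SchemaError(f"outcome table lacks column {col!r}")
        needed = set(spec.survival_covariates) | set(lspec.covariates)
        missing = [c for c in needed if c not in baseline.columns]
        if missing:
            raise SchemaError(f"baseline table lacks columns: {sorted(missing)}")

        self.spec = spec
        out = outcome.set_index("patient_id")
        base = baseline.set_index("patient_id")
        self.pids = sorted(set(longitudinal["patient_id"]) & set(out.index)
                           & set(base.index))
        n = len(self.pids)
        if n == 0:
            raise DegenerateDataError("no patients shared across the three tables")
        self.T = out.loc[self.pids, "event_time"].to_numpy(dtype=float)
        self.delta = (out.loc[self.pids, "event_type"] == "death").to_numpy()
        if np.any(self.T <= 0):
            raise SchemaError("event times must be positive")

        self.basis = lspec.build_basis(longitudinal["t"].to_numpy(dtype=float))
        self.beta_names = design_names(lspec, self.basis)
        self.gamma_names = list(spec.survival_covariates)
        self.W = base.loc[self.pids, self.gamma_names].to_numpy(dtype=float)
        self.cov_rows = {
            pid: (base.loc[pid, list(lspec.covariates)].to_numpy(dtype=float)
                  if lspec.covariates else np.empty(0))
            for pid in self.pids}

        # longitudinal padding
        groups = dict(tuple(longitudinal.groupby("patient_id")))
        M = max(len(groups[pid]) for pid in self.pids)
        p = len(self.beta_names)
        d = 1 + (self.basis.n_cols if lspec.random == "full" else 1)
        self.Y = np.zeros((n, M))
        self.Xl = np.zeros((n, M, p))
        self.Zl = np.zeros((n, M, d))
        self.mask = np.zeros((n, M))
        for i, pid in enumerate(self.pids):
            g = groups[pid].sort_values("t")
            t = g["t"].to_numpy(dtype=float)
            X, Z = build_design(t, self.basis, self.cov_rows[pid], lspec)
            m = len(t)
            self.Y[i, :m] = g[lspec.value_col].to_numpy(dtype=float)
            self.Xl[i, :m] = X
            self.Zl[i, :m] = Z
            self.mask[i, :m] = 1.0
        self.Xl *= self.mask[:, :, None]
        self.Zl *= self.mask[:, :, None]
        self.n_obs = self.mask.sum(axis=1)
        self.ZtZ = np.einsum("nmd,nme->nde", self.Zl, self.Zl)

        # hazard segments at event-time quantiles
        K = spec.n_hazard_segments
        deaths = self.T[self.delta]
        if deaths.size:
            qs = np.quantile(deaths, np.linspace(0, 1, K + 1)[1:-1])
            bnd = np.unique(np.round(np.concatenate([[0.0], qs]), 8))
        else:
            bnd = np.array([0.0])
        self.boundaries = bnd  # segment k spans [bnd[k], bnd[k+1]) (last open)
        self.K = len(bnd)

        # Gauss-Legendre grid on each (patient-truncated) segment
        xi, om = leggauss(spec.gl_nodes)
        Sg, wg = [], []
        for k in range(self.K):
            a = bnd[k]
            upper = bnd[k + 1] if k < self.K - 1 else np.inf
            b_i = np.minimum(self.T, upper)
            width = np.clip(b_i - a, 0.0, None)
            Sg.append(a + width[:, None] * (xi[None, :] + 1.0) / 2.0)
            wg.append(width[:, None] * om[None, :] / 2.0)
        self.Sg = np.concatenate(Sg, axis=1)          # (n, G)
        self.wg = np.concatenate(wg, axis=1)          # (n, G)
        self.segpt = np.repeat(np.arange(self.K), spec.gl_nodes)

        # trajectory designs at quadrature points and at the event time
        G = self.Sg.shape[1]
        self.Xg = np.zeros((n, G, p))
        self.Zg = np.zeros((n, G, d))
        self.dXg = np.zeros((n, G, p))
        self.dZg = np.zeros((n, G, d))
        self.xT = np.zeros((n, p))
        self.zT = np.zeros((n, d))
        self.dxT = np.zeros((n, p))
        self.dzT = np.zeros((n, d))
        for i, pid in enumerate(self.pids):
            cov = self.cov_rows[pid]
            X, Z = build_design(self.Sg[i], self.basis, cov, lspec)
            dX, dZ = build_design_deriv(self.Sg[i], self.basis, cov.size, lspec)
            self.Xg[i], self.Zg[i], self.dXg[i], self.dZg[i] = X, Z, dX, dZ
            X, Z = build_design([self.T[i]], self.basis, cov, lspec)
            dX, dZ = build_design_deriv([self.T[i]], self.basis, cov.size, lspec)
            self.xT[i], self.zT[i] = X[0], Z[0]
            self.dxT[i], self.dzT[i] = dX[0], dZ[0]
        self.segT = np.clip(np.searchsorted(bnd, self.T, side="right") - 1, 0, self.K - 1)

        self.dims = {"p": p, "d": d, "q": len(self.gamma_names), "K": self.K,
                     "n": n}
        u1, w1 = hermgauss(spec.gh_nodes)
        grids = np.meshgrid(*([u1] * d), indexing="ij")
        self.gh_u = np.stack([g.ravel() for g in grids], axis=1)   # (J, d)
        wgrids = np.meshgrid(*([w1] * d), indexing="ij")
        self.gh_w = np.prod(np.stack([g.ravel() for g in wgrids], axis=1), axis=1)


def _batch_inv(M: np.ndarray):
    """Inverse of a stack of SPD matrices; closed form for the 2x2 case."""
    d = M.shape[-1]
    if d == 2:
        a, b, c = M[:, 0, 0], M[:, 0, 1], M[:, 1, 1]
        det = a * c - b * b
        if np.any(det <= 0) or not np.all(np.isfinite(det)):
            return None
        out = np.empty_like(M)
        out[:, 0, 0] = c / det
        out[:, 1, 1] = a / det
        out[:, 0, 1] = out[:, 1, 0] = -b / det
        return out
    try:
        return np.linalg.inv(M)
    except np.linalg.LinAlgError:
        return None


def _batch_chol(M: np.ndarray):
    """Lower Cholesky factor of a stack of SPD matrices (closed-form 2x2)."""
    d = M.shape[-1]
    if d == 2:
        a, b, c = M[:, 0, 0], M[:, 0, 1], M[:, 1, 1]
        if np.any(a <= 0):
            return None
        l11 = np.sqrt(a)
        l21 = b / l11
        rest = c - l21 ** 2
        if np.any(rest <= 0) or not np.all(np.isfinite(rest)):
            return None
        out = np.zeros_like(M)
        out[:, 0, 0] = l11
        out[:, 1, 0] = l21
        out[:, 1, 1] = np.sqrt(rest)
        return out
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        return None


def joint_log_likelihood(params: JointParams, data: JointData,
                         gh_nodes: int | None = None) -> float:
    """Marginal joint log-likelihood (random effects integrated out).

    Per patient: ``log  integral  N(y_i | b) * [h_i(T)^delta * exp(-H_i(T)) | b]
    * N(b; 0, D) db`` with adaptive Gauss-Hermite centred at the patient's
    longitudinal posterior and the log-sum-exp trick for stability.
    """
    d = data.dims["d"]
    if gh_nodes is not None and gh_nodes != data.spec.gh_nodes:
        u1, w1 = hermgauss(gh_nodes)
        grids = np.meshgrid(*([u1] * d), indexing="ij")
        gh_u = np.stack([g.ravel() for g in grids], axis=1)
        wgrids = np.meshgrid(*([w1] * d), indexing="ij")
        gh_w = np.prod(np.stack([g.ravel() for g in wgrids], axis=1), axis=1)
    else:
        gh_u, gh_w = data.gh_u, data.gh_w

    beta, D, sigma = params.beta, params.D, params.sigma
    lam = np.exp(params.log_lambda)
    if d == 2:
        detD = D[0, 0] * D[1, 1] - D[0, 1] * D[1, 0]
        if detD <= 0 or D[0, 0] <= 0:
            return -np.inf
        logdetD = np.log(detD)
        Dinv = np.array([[D[1, 1], -D[0, 1]], [-D[1, 0], D[0, 0]]]) / detD
    else:
        if np.any(np.linalg.eigvalsh(D) <= 0):
            return -np.inf
        Dinv = np.linalg.inv(D)
        _, logdetD = np.linalg.slogdet(D)

    R = (data.Y - data.Xl @ beta) * data.mask
    ZtR = np.einsum("nmd,nm->nd", data.Zl, R)
    RtR = np.einsum("nm,nm->n", R, R)

    A = data.ZtZ / sigma ** 2 + Dinv[None, :, :]
    Sig = _batch_inv(A)
    if Sig is None:
        return -np.inf
    Lp = _batch_chol(Sig)
    if Lp is None:
        return -np.inf
    mu = np.einsum("nde,ne->nd", Sig, ZtR) / sigma ** 2

    linw = data.W @ params.gamma if data.dims["q"] else np.zeros(len(data.T))
    lam_w = data.wg * lam[data.segpt][None, :]

    # adapt the quadrature to the *full* per-patient posterior: a short damped
    # Newton search for its mode (the survival factor tilts it away from the
    # longitudinal-only posterior) and the full curvature as the grid scale
    a_quad = params.alpha_value * data.Zg
    assoc_fix = params.alpha_value * (data.Xg @ beta)
    if params.alpha_slope != 0.0:
        a_quad = a_quad + params.alpha_slope * data.dZg
        assoc_fix = assoc_fix + params.alpha_slope * (data.dXg @ beta)
    event_lin = params.alpha_value * data.zT
    if params.alpha_slope != 0.0:
        event_lin = event_lin + params.alpha_slope * data.dzT
    lin_long = ZtR / sigma ** 2 + data.delta[:, None] * event_lin
    sig_diag = np.sqrt(np.einsum("ndd->nd", Sig))
    mode = mu
    Hess = A
    for _ in range(2):
        assoc_m = np.clip(assoc_fix + np.einsum("ngd,nd->ng", a_quad, mode)
                          + linw[:, None], -200.0, 200.0)
        tilt = lam_w * np.exp(assoc_m)
        grad = (lin_long - np.einsum("nde,ne->nd", A, mode)
                - np.einsum("ng,ngd->nd", tilt, a_quad))
        Hess = A + np.einsum("ng,ngd,nge->nde", tilt, a_quad, a_quad)
        HessInv = _batch_inv(Hess)
        if HessInv is None:
            return -np.inf
        step = np.einsum("nde,ne->nd", HessInv, grad)
        # damp each step to 2 longitudinal-posterior SDs per coordinate
        znorm = np.sqrt(((step / sig_diag) ** 2).sum(axis=1))
        mode = mode + step * np.minimum(1.0, 2.0 / np.maximum(znorm, 1e-12))[:, None]
    Lp = _batch_chol(HessInv)
    if Lp is None:
        return -np.inf

    B = mode[:, None, :] + np.sqrt(2.0) * np.einsum("nde,je->njd", Lp, gh_u)

    quad_long = (RtR[:, None]
                 - 2.0 * np.einsum("njd,nd->nj", B, ZtR)
                 + np.einsum("njd,nde,nje->nj", B, data.ZtZ, B))
    loglong = (-0.5 * data.n_obs[:, None] * np.log(2 * np.pi * sigma ** 2)
               - 0.5 * quad_long / sigma ** 2)
    logprior = (-0.5 * d * np.log(2 * np.pi) - 0.5 * logdetD
                - 0.5 * np.einsum("njd,de,nje->nj", B, Dinv, B))

    assoc = np.clip(assoc_fix[:, None, :]
                    + np.einsum("ngd,njd->njg", a_quad, B), -700.0, 700.0)
    H = np.exp(linw)[:, None] * np.einsum("ng,njg->nj", lam_w, np.exp(assoc))

    assocT_fix = params.alpha_value * (data.xT @ beta)
    if params.alpha_slope != 0.0:
        assocT_fix = assocT_fix + params.alpha_slope * (data.dxT @ beta)
    loghT = (params.log_lambda[data.segT] + linw + assocT_fix)[:, None] \
        + np.einsum("nd,njd->nj", event_lin, B)

    f = loglong + logprior + data.delta[:, None] * loghT - H
    core = np.log(gh_w)[None, :] + np.sum(gh_u ** 2, axis=1)[None, :] + f
    fmax = core.max(axis=1, keepdims=True)
    lse = fmax[:, 0] + np.log(np.sum(np.exp(core - fmax), axis=1))
    logdetLp = np.log(np.einsum("ndd->nd", Lp)).sum(axis=1)
    ll = np.sum(0.5 * d * np.log(2.0) + logdetLp + lse)
    if not np.isfinite(ll):
        bad = np.where(~np.isfinite(lse))[0]
        pid = data.pids[bad[0]] if bad.size else "?"
        raise NumericalError(f"non-finite likelihood contribution (patient {pid})")
    return float(ll)


# --- fitting ----------------------------------------------------------------

@dataclass
class JointModelFit:
    """Everything needed to predict from and report the fitted joint model."""

    spec: JointSpec
    params: JointParams
    beta_names: list
    gamma_names: list
    boundaries: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    message: str
    se: dict = field(default_factory=dict)
    packed: np.ndarray | None = None
    packed_cov: np.ndarray | None = None
    basis_state: dict = field(default_factory=dict)
    n_patients: int = 0
    n_events: int = 0
    two_stage: LongitudinalFit | None = None

    # -- reporting ----------------------------------------------------------
    def hazard_ratios(self, slope_per_30_days: bool = False) -> dict:
        """Per-term multiplicative hazard ratios.

        ``value`` is per MELD-Na point; ``slope`` per point/day internally,
        or per point/30-days when requested.
        """
        out = {}
        if self.spec.use_value:
            out["value"] = float(np.exp(self.params.alpha_value))
        if self.spec.use_slope:
            a = self.params.alpha_slope
            out["slope"] = float(np.exp(a / 30.0)) if slope_per_30_days else float(np.exp(a))
        for name, g in zip(self.gamma_names, self.params.gamma):
            out[name] = float(np.exp(g))
        return out

    def make_basis(self):
        st = self.basis_state
        return make_basis(st["kind"], interior_knots=st.get("interior"),
                          boundary_knots=st.get("boundary"))

    # -- plain-text persistence ---------------------------------------------
    def to_json(self) -> str:
        payload = {
            "format": "aclfjm-joint-fit/1",
            "spec": {
                "longitudinal": asdict(self.spec.longitudinal),
                "survival_covariates": list(self.spec.survival_covariates),
                "n_hazard_segments": self.spec.n_hazard_segments,
                "gh_nodes": self.spec.gh_nodes,
                "gl_nodes": self.spec.gl_nodes,
                "use_value": self.spec.use_value,
                "use_slope": self.spec.use_slope,
            },
            "params": {
                "beta": self.params.beta.tolist(),
                "D": self.params.D.tolist(),
                "sigma": self.params.sigma,
                "gamma": self.params.gamma.tolist(),
                "alpha_value": self.params.alpha_value,
                "alpha_slope": self.params.alpha_slope,
                "log_lambda": self.params.log_lambda.tolist(),
            },
            "beta_names": self.beta_names,
            "gamma_names": self.gamma_names,
            "boundaries": self.boundaries.tolist(),
            "basis_state": {k: (list(v) if isinstance(v, (tuple, np.ndarray)) else v)
                            for k, v in self.basis_state.items()},
            "loglik": self.loglik,
            "converged": self.converged,
            "se": self.se,
            "n_patients": self.n_patients,
            "n_events": self.n_events,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "JointModelFit":
        obj = json.loads(text)
        if obj.get("format") != "aclfjm-joint-fit/1":
            raise SchemaError("not a joint-fit artifact")
        sp = obj["spec"]
        lsp = sp["longitudinal"]
        lsp["covariates"] = tuple(lsp.get("covariates") or ())
        spec = JointSpec(
            longitudinal=LongitudinalSpec(**lsp),
            survival_covariates=tuple(sp["survival_covariates"]),
            n_hazard_segments=sp["n_hazard_segments"], gh_nodes=sp["gh_nodes"],
            gl_nodes=sp["gl_nodes"], use_value=sp["use_value"],
            use_slope=sp["use_slope"])
        pr = obj["params"]
        params = JointParams(
            beta=np.array(pr["beta"]), D=np.array(pr["D"]), sigma=pr["sigma"],
            gamma=np.array(pr["gamma"]), alpha_value=pr["alpha_value"],
            alpha_slope=pr["alpha_slope"], log_lambda=np.array(pr["log_lambda"]))
        return cls(spec=spec, params=params, beta_names=obj["beta_names"],
                   gamma_names=obj["gamma_names"],
                   boundaries=np.array(obj["boundaries"]),
                   loglik=obj["loglik"], converged=obj["converged"], n_iter=0,
                   message="loaded", se=obj.get("se", {}),
                   basis_state=obj.get("basis_state", {}),
                   n_patients=obj.get("n_patients", 0),
                   n_events=obj.get("n_events", 0))


def _basis_state(data: JointData) -> dict:
    basis = data.basis
    if hasattr(basis, "knots"):
        return {"kind": "ns", "interior": list(basis.knots[1:-1]),
                "boundary": [basis.knots[0], basis.knots[-1]]}
    return {"kind": "linear"}


def _two_stage_init(baseline, longitudinal, outcome, spec: JointSpec,
                    data: JointData) -> tuple[JointParams, LongitudinalFit]:
    # the init only needs rough estimates: cap the mixed-model stage at 2000
    # patients (deterministic subsample) for large cohorts
    ids = baseline["patient_id"].to_numpy()
    if len(ids) > 2000:
        sub = np.random.default_rng(0).choice(ids, 2000, replace=False)
        lfit = fit_lmm(longitudinal[longitudinal["patient_id"].isin(set(sub))],
                       spec.longitudinal, baseline)
    else:
        lfit = fit_lmm(longitudinal, spec.longitudinal, baseline)
    q, K = data.dims["q"], data.K

    # crude baseline-hazard init from events / person-time per segment
    gamma = np.zeros(q)
    av, asl = 0.0, 0.0
    log_lam = np.zeros(K)
    bnd = np.append(data.boundaries, np.inf)
    for k in range(K):
        exposure = np.clip(np.minimum(data.T, bnd[k + 1]) - bnd[k], 0, None).sum()
        dk = np.sum(data.delta & (data.segT == k))
        log_lam[k] = np.log(max(dk, 0.5) / max(exposure, 1e-9))

    # PH regression on EB fitted value/slope at the event time
    try:
        from lifelines import CoxPHFitter
        from .lmm import trajectory as _traj
        avail = set(lfit.ranef.index)
        keep = np.array([pid in avail for pid in data.pids])
        vals, slopes = [], []
        for pid, T in zip(np.asarray(data.pids)[keep], data.T[keep]):
            v, s = _traj(lfit, pid, T)
            vals.append(v)
            slopes.append(s)
        df = pd.DataFrame(data.W[keep], columns=data.gamma_names)
        df["value_hat"] = vals
        df["slope_hat"] = slopes
        df["T"] = data.T[keep]
        df["event"] = data.delta[keep].astype(int)
        cph = CoxPHFitter(penalizer=0.01)
        cph.fit(df, duration_col="T", event_col="event")
        coef = cph.params_
        gamma = coef[data.gamma_names].to_numpy()
        if spec.use_value:
            av = float(coef["value_hat"])
        if spec.use_slope:
            asl = float(coef["slope_hat"])
        # recentre baseline hazard for the covariate contribution
        mean_lin = float(np.mean(df[data.gamma_names].to_numpy() @ gamma
                                 + av * df["value_hat"] + asl * df["slope_hat"]))
        log_lam -= mean_lin
    except Exception:  # fall back to null association
        pass

    params = JointParams(beta=lfit.beta.copy(), D=lfit.D.copy(), sigma=lfit.sigma,
                         gamma=gamma, alpha_value=av, alpha_slope=asl,
                         log_lambda=log_lam)
    return params, lfit


def fit_joint_model(baseline: pd.DataFrame, longitudinal: pd.DataFrame,
                    outcome: pd.DataFrame, spec: JointSpec | None = None,
                    init: JointParams | None = None, compute_se: bool = True,
                    maxiter: int = 150, ftol: float = 1e-9) -> JointModelFit:
    """Maximize the joint likelihood by quasi-Newton ascent.

    Initialization defaults to two-stage estimates (mixed-model fit, then a
    proportional-hazards regression on its fitted values).  Standard errors
    come from the observed information (central-difference Hessian of the
    log-likelihood at the optimum).
    """
    spec = spec or JointSpec()
    data = JointData(baseline, longitudinal, outcome, spec)
    if not np.any(data.delta):
        raise DegenerateDataError(
            "no death events in the data: gamma and the association "
            "parameters are inestimable")

    two_stage_fit = None
    if init is None:
        init, two_stage_fit = _two_stage_init(baseline, longitudinal, outcome,
                                              spec, data)
    x0 = pack_params(init, spec)

    def negll(x):
        try:
            return -joint_log_likelihood(unpack_params(x, data.dims, spec), data)
        except (NumericalError, np.linalg.LinAlgError):
            return 1e12

    # quasi-Newton ascent with restart polishing: re-running from the
    # solution clears stale curvature memory and guards against premature
    # line-search stops on this ill-conditioned surface
    x = x0
    f_prev = np.inf
    for _round in range(3):
        res = optimize.minimize(negll, x, method="L-BFGS-B",
                                options={"maxiter": maxiter, "ftol": ftol,
                                         "gtol": 1e-5, "maxcor": 40})
        x = res.x
        if f_prev - res.fun < 1e-6 * (1.0 + abs(res.fun)):
            break
        f_prev = res.fun
    ll = -float(res.fun)
    grad_ok = np.max(np.abs(res.jac)) < 1e-2 * (1.0 + abs(ll))
    converged = bool(res.success or grad_ok)
    params = unpack_params(res.x, data.dims, spec)
    if not np.isfinite(ll):
        raise NonConvergenceError("joint fit diverged", trace=res)
    fit = JointModelFit(
        spec=spec, params=params, beta_names=data.beta_names,
        gamma_names=data.gamma_names, boundaries=data.boundaries.copy(),
        loglik=ll, converged=converged, n_iter=int(res.nit),
        message=str(res.message), packed=res.x.copy(),
        basis_state=_basis_state(data), n_patients=data.dims["n"],
        n_events=int(data.delta.sum()), two_stage=two_stage_fit)
    if not converged:
        err = NonConvergenceError(
            f"joint fit did not converge: {res.message}", trace=res)
        err.two_stage = two_stage_fit
        err.partial_fit = fit
        raise err

    if compute_se:
        fit.packed_cov, fit.se = _observed_information(res.x, data, spec, negll)
    return fit


def _observed_information(x, data: JointData, spec: JointSpec, negll):
    """SEs from a central-difference Hessian of the negative log-likelihood."""
    k = len(x)
    h = 1e-4 * (1.0 + np.abs(x))
    Hm = np.zeros((k, k))
    f0 = negll(x)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        fpp = negll(x + ei); fmm = negll(x - ei)
        Hm[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(k); ej[j] = h[j]
            fpq = negll(x + ei + ej)
            fpm = negll(x + ei - ej)
            fmp = negll(x - ei + ej)
            fmq = negll(x - ei - ej)
            Hm[i, j] = Hm[j, i] = (fpq - fpm - fmp + fmq) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(Hm)
        ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        ses = np.full(k, np.nan)
    names = packed_names(data.dims, spec, data.beta_names, data.gamma_names)
    return cov, {name: float(s) for name, s in zip(names, ses)}


def packed_names(dims, spec: JointSpec, beta_names, gamma_names):
    d = dims["d"]
    names = [f"beta_{n}" for n in beta_names]
    for i in range(d):
        for j in range(i + 1):
            names.append(f"cholD_{i}{j}" + ("_log" if i == j else ""))
    names.append("log_sigma")
    names += [f"gamma_{n}" for n in gamma_names]
    if spec.use_value:
        names.append("alpha_value")
    if spec.use_slope:
        names.append("alpha_slope")
    names += [f"log_lambda_{k}" for k in range(dims["K"])]
    return names
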