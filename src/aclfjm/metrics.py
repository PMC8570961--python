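"""Landmarked discrimination and calibration metrics.

At a landmark t and horizon h the questions are: among patients still on the
list at t, does the model rank the ones who die in (t, t+h] above the ones
who survive past t+h (time-dependent AUC), and how far are the predicted
survival probabilities from what happened (Brier-type prediction error)?
Both metrics weight by the inverse probability of censoring (IPCW), with the
censoring distribution estimated by Kaplan-Meier on the at-risk set, so
patients censored inside the window contribute through reweighting instead
of being dropped.

`compare_models` evaluates the joint model against the benchmark used for
allocation today: a Cox model on the single most recent MELD-Na score, which
by construction ignores all previous measurements.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

from .joint import JointModelFit
from .predict import PlugInPredictor


class UndefinedMetricError(ValueError):
    pass


# --- censoring distribution -------------------------------------------------

def _censoring_survival(T, is_death, eval_times, entry_time=0.0):
    """G(x)/G(entry): Kaplan-Meier of the censoring distribution, conditioned
    on being uncensored at the entry (landmark) time."""
    km = KaplanMeierFitter()
    km.fit(T, event_observed=~np.asarray(is_death, dtype=bool))
    G = km.survival_function_at_times(np.asarray(eval_times)).to_numpy()
    G0 = float(km.survival_function_at_times([entry_time]).iloc[0]) if entry_time > 0 else 1.0
    if G0 <= 0:
        raise UndefinedMetricError("censoring distribution vanishes at the landmark")
    return G / G0


def dynamic_auc(risk, event_time, is_death, t, horizon):
    """IPCW time-dependent AUC at landmark t for deaths within (t, t+horizon].

    ``risk`` is any score that is higher for sicker patients (AUC is
    invariant to strictly monotone transforms of it).  Cases are subjects
    dying inside the window; controls survive past t+horizon; pairs are
    weighted by the inverse censoring probabilities.  Raises
    :class:`UndefinedMetricError` when either group is empty rather than
    silently returning 0.5.
    """
    risk = np.asarray(risk, dtype=float)
    T = np.asarray(event_time, dtype=float)
    dead = np.asarray(is_death, dtype=bool)
    if not np.all(np.isfinite(risk)):
        raise UndefinedMetricError("non-finite risk scores")
    at_risk = T > t
    risk, T, dead = risk[at_risk], T[at_risk], dead[at_risk]
    u = t + horizon
    cases = dead & (T <= u)
    controls = T > u
    if cases.sum() == 0:
        raise UndefinedMetricError(f"no deaths in ({t}, {u}]")
    if controls.sum() == 0:
        raise UndefinedMetricError(f"no subjects survive past {u}")
    # IPCW: case weight 1/G(T-), control weight 1/G(u) (constant, cancels)
    Gc = _censoring_survival(T, dead, np.maximum(T[cases] - 1e-9, t), entry_time=t)
    if np.any(Gc <= 0):
        raise UndefinedMetricError("censoring KM vanishes before a death time")
    w_case = 1.0 / Gc
    r_case = risk[cases]
    r_ctrl = risk[controls]
    gt = (r_case[:, None] > r_ctrl[None, :]).sum(axis=1).astype(float)
    eq = (r_case[:, None] == r_ctrl[None, :]).sum(axis=1).astype(float)
    conc = np.sum(w_case * (gt + 0.5 * eq))
    total = np.sum(w_case) * len(r_ctrl)
    return float(conc / total)


def prediction_error(pi_pred, event_time, is_death, t, horizon):
    """IPCW Brier-type prediction error at landmark t, horizon h.

    ``pi_pred`` is the predicted probability of surviving to t+h given
    survival to t.  Weights: deaths before t+h get 1/G(T-), survivors get
    1/G(t+h), in-window censored subjects get 0.  With no censoring all
    weights are 1 and this is the plain Brier score.
    """
    pi = np.asarray(pi_pred, dtype=float)
    T = np.asarray(event_time, dtype=float)
    dead = np.asarray(is_death, dtype=bool)
    at_risk = T > t
    pi, T, dead = pi[at_risk], T[at_risk], dead[at_risk]
    u = t + horizon
    died = dead & (T <= u)
    surv = T > u
    w = np.zeros(len(T))
    if died.any():
        Gd = _censoring_survival(T, dead, np.maximum(T[died] - 1e-9, t), entry_time=t)
        if np.any(Gd <= 0):
            raise UndefinedMetricError("censoring KM vanishes before a death time")
        w[died] = 1.0 / Gd
    Gu = _censoring_survival(T, dead, [u], entry_time=t)[0]
    if surv.any() and Gu <= 0:
        raise UndefinedMetricError(f"censoring KM vanishes at horizon {u}")
    w[surv] = 1.0 / Gu if Gu > 0 else 0.0
    outcome_alive = surv.astype(float)
    return float(np.mean(w * (outcome_alive - pi) ** 2))


def bootstrap_ci(metric_fn, data: pd.DataFrame, n_boot: int = 500,
                 seed: int = 0, max_failures: float = 0.10):
    """Percentile bootstrap interval over patient-level resamples.

    ``metric_fn`` maps a resampled DataFrame to a scalar.  Raises if the
    metric is undefined in more than ``max_failures`` of the resamples.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    n = len(data)
    vals, failures = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            vals.append(metric_fn(data.iloc[idx]))
        except UndefinedMetricError:
            failures += 1
    if failures > max_failures * n_boot:
        raise UndefinedMetricError(
            f"metric undefined in {failures}/{n_boot} bootstrap resamples")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


# --- model comparison grid --------------------------------------------------

@dataclass
class LandmarkEvaluation:
    landmark: float
    horizon: float
    model: str
    auc: float
    auc_ci: tuple
    prediction_error: float
    pe_ci: tuple
    n_at_risk: int
    n_events: int


def _last_value_at(longitudinal: pd.DataFrame, t: float, value_col="meld_na"):
    obs = longitudinal[longitudinal["t"] <= t + 1e-12]
    last = obs.sort_values("t").groupby("patient_id").tail(1)
    return last.set_index("patient_id")[value_col]


def fit_meldna_benchmark(longitudinal: pd.DataFrame, outcome: pd.DataFrame):
    """Cox model on the baseline MELD-Na alone (the current-allocation
    benchmark: one number, no history)."""
    score0 = _last_value_at(longitudinal, 0.0)
    df = outcome.set_index("patient_id").join(score0.rename("meld_na")).dropna()
    df["event"] = (df["event_type"] == "death").astype(int)
    cph = CoxPHFitter()
    cph.fit(df[["event_time", "event", "meld_na"]], duration_col="event_time",
            event_col="event")
    return cph


def _benchmark_survival(cph, scores: pd.Series, t: float, u: float) -> pd.Series:
    """Conditional S(u)/S(t) from the benchmark Cox fit at the given scores."""
    X = pd.DataFrame({"meld_na": scores.to_numpy()}, index=scores.index)
    sf = cph.predict_survival_function(X, times=[max(t, 1e-9), u])
    s = sf.T.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(s[:, 0] > 0, s[:, 1] / s[:, 0], 0.0)
    return pd.Series(cond, index=scores.index)


def compare_models(test_baseline, test_longitudinal, test_outcome,
                   jm_fit: JointModelFit, landmarks=(0.0, 2.0, 7.0, 14.0),
                   horizons=(28.0, 90.0), train_longitudinal=None,
                   train_outcome=None, n_boot: int = 200, seed: int = 0,
                   with_ci: bool = True) -> pd.DataFrame:
    """Full landmark x horizon x model grid of AUC and prediction error.

    The benchmark Cox model on the latest MELD-Na is fitted on the training
    tables when given (test tables otherwise).  Bootstrap CIs use shared
    patient-level resamples for both models, so AUC differences can be read
    as paired.
    """
    pred = PlugInPredictor(jm_fit, test_baseline, test_longitudinal)
    bench = fit_meldna_benchmark(
        train_longitudinal if train_longitudinal is not None else test_longitudinal,
        train_outcome if train_outcome is not None else test_outcome)
    out = test_outcome.set_index("patient_id")
    rows = []
    for t in landmarks:
        pi_ids = pred._index
        at_risk_ids = out.index[(out["event_time"] > t)].intersection(pi_ids)
        if len(at_risk_ids) == 0:
            for h in horizons:
                for model in ("aclf_jm", "meld_na"):
                    rows.append(LandmarkEvaluation(
                        t, h, model, np.nan, (np.nan, np.nan), np.nan,
                        (np.nan, np.nan), 0, 0).__dict__
                        | {"note": "no subjects at risk at the landmark"})
            continue
        scores_t = _last_value_at(test_longitudinal, t).reindex(at_risk_ids)
        T = out.loc[at_risk_ids, "event_time"].to_numpy(dtype=float)
        dead = (out.loc[at_risk_ids, "event_type"] == "death").to_numpy()
        for h in horizons:
            pi_jm = pred.survival(t, h).reindex(at_risk_ids).to_numpy()
            pi_mn = _benchmark_survival(bench, scores_t, t, t + h).to_numpy()
            frame = pd.DataFrame({
                "T": T, "dead": dead, "risk_jm": 1.0 - pi_jm, "pi_jm": pi_jm,
                "risk_mn": scores_t.to_numpy(dtype=float), "pi_mn": pi_mn,
            })
            for model, rcol, pcol in (("aclf_jm", "risk_jm", "pi_jm"),
                                      ("meld_na", "risk_mn", "pi_mn")):
                try:
                    auc = dynamic_auc(frame[rcol], frame["T"], frame["dead"], t, h)
                    pe = prediction_error(frame[pcol], frame["T"], frame["dead"], t, h)
                except UndefinedMetricError as exc:
                    rows.append(LandmarkEvaluation(t, h, model, np.nan,
                                                   (np.nan, np.nan), np.nan,
                                                   (np.nan, np.nan),
                                                   len(frame), 0).__dict__
                                | {"note": str(exc)})
                    continue
                auc_ci = pe_ci = (np.nan, np.nan)
                if with_ci:
                    auc_ci = bootstrap_ci(
                        lambda df, rc=rcol: dynamic_auc(df[rc], df["T"], df["dead"], t, h),
                        frame, n_boot=n_boot, seed=seed)
                    pe_ci = bootstrap_ci(
                        lambda df, pc=pcol: prediction_error(df[pc], df["T"], df["dead"], t, h),
                        frame, n_boot=n_boot, seed=seed)
                rows.append(LandmarkEvaluation(
                    t, h, model, auc, auc_ci, pe, pe_ci, len(frame),
                    int((frame["dead"] & (frame["T"] <= t + h)).sum())).__dict__)
    res = pd.DataFrame(rows)
    res[["auc_lo", "auc_hi"]] = pd.DataFrame(res["auc_ci"].tolist(), index=res.index)
    res[["pe_lo", "pe_hi"]] = pd.DataFrame(res["pe_ci"].tolist(), index=res.index)
    return res.drop(columns=["auc_ci", "pe_ci"])


def auc_by_grade(test_baseline, test_longitudinal, test_outcome,
                 jm_fit: JointModelFit, t=0.0, horizon=90.0,
                 grade_col="aclf_grade") -> pd.DataFrame:
    """AUC of both models stratified by baseline ACLF grade."""
    pred = PlugInPredictor(jm_fit, test_baseline, test_longitudinal)
    out = test_outcome.set_index("patient_id")
    base = test_baseline.set_index("patient_id")
    rows = []
    for grade, ids in base.groupby(grade_col).groups.items():
        ids = pd.Index(ids).intersection(pred._index).intersection(out.index)
        ids = ids[out.loc[ids, "event_time"] > t]
        if len(ids) < 10:
            continue
        T = out.loc[ids, "event_time"].to_numpy(dtype=float)
        dead = (out.loc[ids, "event_type"] == "death").to_numpy()
        pi = pred.survival(t, horizon).reindex(ids).to_numpy()
        score = _last_value_at(test_longitudinal, t).reindex(ids).to_numpy(dtype=float)
        for model, risk in (("aclf_jm", 1.0 - pi), ("meld_na", score)):
            try:
                auc = dynamic_auc(risk, T, dead, t, horizon)
            except UndefinedMetricError:
                auc = np.nan
            rows.append({"aclf_grade": grade, "model": model, "auc": auc,
                         "n": len(ids)})
    return pd.DataFrame(rows)
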