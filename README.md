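# aclfjm — dynamic survival prediction for acute-on-chronic liver failure

Acute-on-chronic liver failure (ACLF) is an acute deterioration of chronic
liver disease with failure of one or more organ systems and high short-term
mortality. The MELD-Na score that ranks candidates for liver
transplantation uses only the most recent measurement, so it ignores how
fast a patient is deteriorating — and systematically underestimates risk in
ACLF. This package implements the alternative: a **joint model** that
couples a mixed-effects model of each patient's repeated MELD-Na
measurements to a proportional-hazards model of waitlist death through the
trajectory's *current value* and *current slope*,

```
y_ij   = m_i(t_ij) + e_ij,          m_i(t) = x_i(t)'β + z_i(t)'b_i,   b_i ~ N(0, D)
h_i(t) = h0(t) · exp( γ'w_i + α_value·m_i(t) + α_slope·m_i'(t) )
```

and turns the fit into updating, patient-specific survival predictions
π_i(u|t) — the probability of surviving to day u given survival and all
measurements up to day t.

It is written for biostatisticians and transplant-outcomes researchers who
want to study value-plus-slope risk prediction and its allocation
consequences end to end: clinical scoring, model fitting, dynamic
prediction, landmarked validation, and a counterfactual graft-allocation
experiment, all runnable on synthetic registry-like cohorts (the registry
data such models are built on is access-restricted).

## What's inside

| module | what it does |
| --- | --- |
| `aclfjm.scoring` | MELD / MELD-Na (UNOS formula, clamping, 6–40) and the six EF-Clif organ-failure flags with ACLF grade 0–3 |
| `aclfjm.simulate` | synthetic waitlist cohorts with the exact statistical structure the model assumes; named presets freeze study conditions |
| `aclfjm.lmm` | the mixed-effects MELD-Na submodel (closed-form marginal likelihood, EB trajectories, analytic slopes) |
| `aclfjm.joint` | the joint likelihood (adaptive Gauss–Hermite × Gauss–Legendre), fitting, hazard ratios, the published-coefficient fixture |
| `aclfjm.predict` | dynamic predictions π(u\|t): importance-sampling and plug-in modes, cohort-scale batch predictor |
| `aclfjm.metrics` | landmarked IPCW time-dependent AUC and Brier-type prediction error vs the last-value MELD-Na Cox benchmark, bootstrap CIs |
| `aclfjm.allocation` | graft-offer re-ranking experiment and the four-group priority classification |
| `aclfjm.pipeline` / `aclfjm.cli` | end-to-end runner with manifest; `aclf-jm simulate/score/fit/predict/validate/allocate/run-all` |

## Worked example

The fitted registry model is summarized by per-term hazard-ratio
multipliers; the package ships them as an immutable fixture for worked
examples and a demo predictor:

```python
>>> from aclfjm import load_published_demo, hazard_ratio
>>> demo = load_published_demo()
>>> hazard_ratio(demo, {"value": 1.0})      # +1 MELD-Na point, all else equal
1.15
>>> hazard_ratio(demo, {"aclf3": 1.0})      # ACLF grade 3 vs no ACLF
5.9
>>> hazard_ratio(demo, {"value": 1.0, "slope": 1.0})   # log-linear product
1.173
```

So two otherwise identical candidates differing by one MELD-Na point differ
15% in death hazard, an ACLF-3 patient carries 5.9× the hazard of a
no-ACLF patient, and effects multiply on the hazard scale.

A full synthetic experiment:

```python
from aclfjm import run_experiment
res = run_experiment({"seed": 1, "simulate": {"n_patients": 2000}},
                     outdir="results_run")
print(res["validation"][["landmark", "horizon", "model", "auc"]].head(4))
```

```
   landmark  horizon    model       auc
0         0       28  aclf_jm  0.889501
1         0       28  meld_na  0.873926
2         0       90  aclf_jm  0.875862
3         0       90  meld_na  0.867333
```

The joint model out-discriminates the latest-score benchmark at the same
landmark because it smooths measurement noise, uses the baseline
covariates, and prices in the slope. `results_run/` then contains the
cohort CSVs, the plain-text fit artifact, the validation grid, the
four-group priority table with 28-day mortality per group, figures, and a
`manifest.json` tying everything to the config hash and seed.

The same flow from the shell:

```bash
aclf-jm simulate --preset default --n-patients 2000 --seed 1 --outdir cohort
aclf-jm fit --baseline cohort/baseline.csv --longitudinal cohort/longitudinal.csv \
            --outcome cohort/outcome.csv --out fit.json
aclf-jm predict --fit fit.json --baseline cohort/baseline.csv \
                --measurements cohort/longitudinal.csv -t 14 --horizon 90
```

See `docs/methods.md` for the model, numerics, what the synthetic cohorts
do and do not emulate, and known limitations.

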