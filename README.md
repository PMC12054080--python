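# vancoauc

Four ways to predict 24-hour vancomycin exposure (AUC24) in sepsis
patients — a population-pharmacokinetic model, MAP-Bayesian forecasting,
a random-forest concentration model, and a hybrid model that feeds
individual PK parameters into the forest — together with the
modified-trapezoidal AUC24 calculation, a Laplace nonlinear
mixed-effects fitter, and a synthetic ICU-cohort generator that makes
the whole pipeline testable end to end without any patient data.

The package is aimed at pharmacometricians and clinical-pharmacology
data scientists who want to study when a concentration-free predictor
(covariates only, or covariates + machine learning) is good enough, and
how much measuring a level buys via Bayesian forecasting.

## The models

**Population PK.** One-compartment kinetics with zero-order IV infusion
and first-order elimination. The covariate model for a subject with
creatinine clearance CLCR (mL/min), Charlson index CCI and weight WT (kg):

    CL = 3.35 · (CLCR/93)^0.997 · exp(−0.151 · CCI/5.62) · e^η₁   [L/h]
    V  = 98.5 · (WT/84)^0.205 · e^η₂                              [L]

with lognormal inter-individual variability η ~ N(0, ω²) and a combined
residual-error model C_obs = C_pred·(1+ε) + ε₁. (The source literature
prints the typical clearance as "3.35 mL/min"; this package uses L/h
throughout — see `docs/methods.md`.)

**Exposure.** AUC24 from a peak/trough pair (Cmax drawn 1–2 h after a
dose, Cmin 0.5–1 h before the next) by the modified trapezoid

    AUC24 = ( t_inf·(Cmax+Cmin)/2 + (Cmax−Cmin)·Δt / (ln Cmax − ln Cmin) ) · n

where t_inf is the infusion duration, Δt the time between the samples
and n the doses per 24 h.

**The four predictors.** `ppk` evaluates the covariate model at η = 0;
`bayesian` estimates η by posterior mode (MAP) from the subject's
measured concentrations; `ml` is a random forest trained to predict
concentration from TAD, DOSE24, WT, age, HCT, RBC, hemoglobin and CLCR;
`hybrid` replaces part of that feature set with the individual CL and V
(TAD, DOSE24, CL, V, age, WT, HCT, hemoglobin). Each produces a
(Cmax, Cmin) pair that goes through the same trapezoid. Predictions are
scored with MAE, MSE, RMSE, MAPE, R² and F30 (the percentage of
predictions within ±30% relative error).

## Worked example

```python
from vancoauc import (PopulationModel, Covariates, typical_params,
                      predict_peak_trough, auc24_modified_trapezoid)
from vancoauc.pk import Regimen

pop = PopulationModel()                       # the published final model
cov = Covariates(clcr=93, cci=0, wt=84)       # reference patient
params = typical_params(pop.fixed, cov)
print(params.cl, params.v)                    # 3.35 98.5

reg = Regimen.intermittent(1000, 12, 1.0, 10) # 1000 mg q12h, 1 h infusions
cmax, cmin = predict_peak_trough(params, reg, 109.0, 119.5)
print(round(cmax, 2), round(cmin, 2))         # 29.28 20.49
auc = auc24_modified_trapezoid(cmax, cmin, 1.0, 10.5, 2)
print(round(auc, 1))                          # 566.9  (Dose24/CL = 597.0)
```

The typical patient clears 3.35 L/h and distributes into 98.5 L; on
1000 mg q12h the model-exact peak/trough pair after ten doses is about
29 → 20 mg/L, and the trapezoid estimates an AUC24 of ~567 mg·h/L —
inside the usual 400–600 mg·h/L target range and, as expected for a
pair that does not cover the full interval, a little under the exact
steady-state value Dose24/CL = 597 mg·h/L.

The full study pipeline lives in `analysis/`:

```bash
python analysis/01_simulate_cohort.py    # 4,059 virtual subjects, ~1.6% with a peak/trough pair
python analysis/02_fit_ppk.py            # simulate-and-refit parameter recovery
python analysis/03_train_ml.py           # 8-learner benchmark, Boruta, attributions, tuning
python analysis/04_benchmark_methods.py  # the 4-method comparison over 20 seeds
```

`04` prints the seed-averaged testing-set comparison; on the default
seeds the mean MAE ordering is bayesian (56) < hybrid (196) ≤ ml (199)
< ppk (218) mg·h/L, with the Bayesian forecaster reaching F30 ≈ 99%
while the concentration-free methods sit between 65 and 71%. `03`
reproduces the feature-importance finding that CLCR dominates the plain
forest while CL dominates the hybrid model.

A `vancoauc` CLI wraps the same stages (`simulate`, `fit-ppk`, `map`,
`train-ml`, `benchmark`, `report`); every run logs its seed and config
hash.

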