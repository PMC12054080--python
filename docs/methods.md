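# Methods

## Kinetic model

All concentration predictions come from the closed-form solution of
one-compartment kinetics with zero-order IV infusion and first-order
elimination. For a single infusion at rate R₀ = dose/t_inf starting at
time 0, with clearance CL (L/h), volume V (L) and k = CL/V:

    C(t) = (R₀/CL)·(1 − e^{−k·min(t, t_inf)})·e^{−k·max(t − t_inf, 0)}

Multiple doses superpose (linear kinetics); the superposition is
verified against stiff ODE integration of dA/dt = R_in(t) − kA to a
relative accuracy of 1e−6 in the test suite. Two-compartment kinetics,
nonlinear elimination and oral absorption are out of scope.

**Units.** Doses in mg, times in hours, CL in L/h, V in L,
concentrations in mg/L, AUC24 in mg·h/L. The source literature prints
the typical clearance as "3.35 mL/min"; 3.35 mL/min (≈0.2 L/h) would
give a typical vancomycin AUC24 of ~10,000 mg·h/L, which is not a
credible exposure, so the value is interpreted as 3.35 L/h. The number
itself is reported unchanged.

## Population model

Typical values follow the covariate model (power terms for CLCR on CL
and WT on V, an exponential term for CCI on CL, references 93 mL/min,
5.62 and 84 kg — treated as fixed constants of the model, not
re-estimated). Inter-individual variability is lognormal,
P_i = TV·e^η with η ~ N(0, ω²); four residual-error models (additive,
proportional, combined, exponential) are implemented, the combined
model being the default everywhere.

The body of the source reports no ω² or δ² values (they sit in an
unavailable supplement), so the package defaults are typical vancomycin
population-PK magnitudes: ω² = 0.09 on both CL and V (30% CV),
proportional residual SD 20%, additive residual SD 1 mg/L. They are
used both to simulate and as fitting initials, and every one is
overridable through `VarianceComponents`.

"Typical CL = 3.35" is read as the equation evaluated with every
covariate multiplier at one (CLCR = 93, CCI = 0); the alternative
reading (CCI at its mean) gives 3.35·e^{−0.151} ≈ 2.88 and is not used,
but both evaluations appear as tested worked examples.

## Exposure (AUC24)

The peak/trough trapezoid combines a linear trapezoid over the infusion
window with a log-trapezoid (log-mean concentration × Δt) over the
elimination window, times the number of doses per 24 h. The log gap
ln Cmax − ln Cmin is computed as −log1p((Cmin−Cmax)/Cmax), which is
cancellation-free, and below a gap of 1e−12 the log-mean is replaced by
the arithmetic mean (the continuous limit). Because the formula only
covers t_inf + Δt of each interval, it underestimates the exact
steady-state value Dose24/CL by a few percent when the pair is drawn
inside the clinical windows; tests bound this method error at 15% for
end-of-infusion-anchored pairs at steady state. The same formula applied
to the *measured* pair defines the reference ("true") AUC24 a
prediction is scored against, matching clinical practice. If noise
inverts a flat pair (measured peak < trough), the values are reordered
before the formula is applied.

## Estimation

**MAP forecasting.** For one subject, the posterior mode of η minimises

    g(η) = Σ_j [ (y_j − f_j(η))²/v_j(η) + ln v_j(η) ] + η_CL²/ω²_CL + η_V²/ω²_V

with v_j the residual-error variance at the prediction. The solver is a
damped Newton iteration on the 2-d η with a 9-point finite-difference
stencil (h = 1e−4), a proportional Levenberg shift when the Hessian is
indefinite, a trust region of 2 log-units per step (rescaling the whole
step, never clipping componentwise, which would corrupt the descent
direction), per-subject backtracking, and a gradient tolerance of 1e−6.
With no observations the prior mode η = 0 (typical values) is returned.
The optimizer is validated against a grid search and, in the near-
Gaussian regime, against Gauss–Hermite quadrature.

**Population fitting.** Marginal maximum likelihood by the Laplace
approximation: −2·log L per subject is g(η̂) + n·ln 2π + Σ ln ω² +
ln det(∇²g(η̂)/2), with the inner solve vectorised across all subjects
(padded arrays, one tensor evaluation per stencil). This is a
Laplace objective, not a bit-for-bit NONMEM FOCE-I emulation; in the
recovery regimes tested the two are equivalent in the quantities that
matter. Numerical guards: variances are estimated on the log scale with
a floor of 1e−8; the Laplace log-determinant floors det(H/2) at 1e−8
(a near-singular Hessian means a flat posterior direction, and an
unfloored determinant would reward degenerate variance configurations);
box bounds keep CL in [0.05, 100] L/h, V in [5, 2000] L, coefficients
in ±5, IIV variances ≤ 10 and residual variances ≤ 1e3. The outer
search is L-BFGS-B (gradient tolerance 1e−5) in two stages — typical
values and covariate coefficients first at the initial variances, then
everything jointly — because a joint cold start can walk the variance
components into a degenerate corner before the structural parameters are
anywhere near the data. The inner solve always restarts from η = 0 so
the objective is a pure function of the outer parameters (a warm start
makes it history-dependent and breaks the line search).

**Stepwise covariate search** adds the candidate with the largest OFV
drop while the drop exceeds 3.84 (χ²₁ at 0.05) and then removes
covariates whose loss is below 6.63 (χ²₁ at 0.01) — the conventional
cutoffs, since no thresholds are reported. Ties break by candidate
order. **Bootstrap validation** resamples subjects with replacement,
refits starting at the reference estimates, reports medians and
2.5/97.5 percentiles, and flags whether the reference estimates fall
inside the intervals; non-converged replicates are dropped and counted.

## Machine learning

Feature tables have one row per concentration observation; TAD is the
time since the most recent dose start and observations with no
preceding dose are excluded. The two feature sets are fixed by the
study design: TAD, DOSE24, WT, age, HCT, RBC, hemoglobin, CLCR for the
plain model; TAD, DOSE24, CL, V, age, WT, HCT, hemoglobin for the
hybrid (RBC is present only in the first list and CLCR only in the
first — reproduced exactly as published). At test time the hybrid's
CL/V default to the covariate-only typical values so the
concentration-free scenario stays honest; `pk_source="map"` switches to
MAP-estimated values for sensitivity analyses (this leaks the measured
concentrations into the features, which is one reading of the original
design and therefore kept available but off).

Eight learners (elastic net, kNN, linear, single-hidden-layer neural
network, random forest, decision tree, SVR, XGBoost) are benchmarked by
k-fold cross-validation with folds grouped by subject, so one subject's
observations never straddle a fold — the original grouping is not
reported, and ungrouped folds would leak subject identity. Forest
defaults: 500 trees, unlimited depth, features-per-split p/3; the
tuning grid is trees {100, 500, 1000} × depth {4, 8, ∞} × min-leaf
{1, 5, 10} with the default configuration always included, so tuning
can never reduce the cross-validated R². Boruta-style screening
compares each feature's forest importance against the best of the
permuted shadow copies over ≥20 iterations and classifies by a
Bonferroni-corrected binomial test. Per-sample attributions are exact
path decompositions for trees and forests (the change in node value at
each split is credited to the split feature, so attributions sum to
prediction minus baseline) and coefficient × centred-value for linear
models; permutation importance is the non-additive fallback. Negative
concentration predictions are clipped to zero.

## Synthetic cohort generator

Covariates are drawn from a Gaussian copula over truncated-normal
marginals whose *parent* parameters are moment-matched so the truncated
draws reproduce the target mean and SD (truncating N(93, 66²) at
10 mL/min verbatim would inflate the CLCR mean by ~13). Defaults follow
the tabulated sepsis-cohort marginals (age 65.4 ± 15.8 y, weight
82.6 ± 25.4 kg, CLCR 93.3 ± 66.2 mL/min, CCI 5.62 ± 3.10, HCT
29.6 ± 5.2%, hemoglobin 9.5 ± 1.7 g/dL, RBC 3.24 ± 0.62, 58.8% male).
Only marginals are published, so correlations are modelling
assumptions: +0.3 among weight/RBC/hemoglobin/HCT, −0.4 between CLCR
and age, zero otherwise. CLCR is drawn directly rather than derived
from creatinine because the cohort table reports it directly.

Regimens are drawn from weighted options (default 1000 mg q12h 60%,
1500 mg q12h 40%, infusion 1–2 h, 8 doses ≈ 4 days). Sampling follows a
policy: ~1.5% of subjects receive a qualifying peak/trough pair (peak
1–2 h after a dose, trough 0.5–1 h before the next, same interval) —
echoing the 53-of-4,059 testing fraction — and the rest receive 1–4
sparse TDM samples in distinct intervals, 60% troughs, 20% unpaired
peak-window draws, 20% mid-interval. The unpaired peaks matter: without
any peak-phase rows in training, the ML arms must extrapolate at
exactly the times they are scored on. A separate `rich` design for
parameter-recovery studies places end-of-infusion samples in four
different intervals plus a mid-interval and a pre-dose sample; designs
with all samples in one interval leave the weight exponent on V with a
standard error (~0.08) too wide for a ±0.10 recovery check, while this
design achieves ~0.05.

The generator stores true η, CL, V and the exact steady-state AUC24
(Dose24/CL_true) as a hidden-truth sidecar that no estimator reads.
Observed concentrations get combined residual noise and are floored at
0.01 mg/L (an assay cannot report a negative level; the floor is rare
enough not to distort the likelihood).

**Misspecification.** With `MisspecConfig.off()` the generator equals
the analysis model, and the self-consistency results hold (the fitter
recovers the generating parameters; the Bayesian method dominates). The
default-on configuration deviates in two ways: a hidden hematocrit
effect on CL (×0.75 per SD of HCT — a covariate the mechanistic model
does not carry but the ML feature sets do) and a 10% lognormal
inter-interval CL wobble (intra-individual variability beyond the
residual model, applied per observation). The HCT magnitude was
calibrated by pilot runs as the smallest tried value for which the
seed-averaged testing-set MAE ordering bayesian < hybrid ≤ ml < ppk is
robust; at −15%/SD the margin between the forests and the mechanistic
model is within seed noise. A Student-t option for heavy-tailed η
exists and defaults off. These are assumptions, not reconstructions —
the original regimens and sampling-time distributions are not reported.

**Missingness.** The imputation stage injects missing-completely-at-
random gaps per column, drops any column above 20% missing, and fills
the rest with an iterative conditional imputer whose per-column learner
is a regression tree (CART), mirroring tree-based MICE.

## Evaluation

MAE, MSE, RMSE = √MSE, MAPE = 100·mean(|ŷ−y|/y), R² = 1 − SSE/SST with
SST about the mean of the true values, and F30 = 100·fraction with
|ŷ−y|/y ≤ 0.30. MAPE divides by the true value even though one printed
form of the formula omits the division — the reported quantities are
percentages of actual values, which requires it. R² is computed
directly from SSE/SST; the SST = SSR + SSE identity holds only for
fitted least-squares regressions and is not assumed. R² is undefined
(NaN) when all true values coincide.

## Problem sizes and runtime

The reference computations are sized for a desk machine: the
parameter-recovery study uses 500 subjects × 6 samples (one fit ≈ 30 s;
recovery of θ_CL/θ_V within 10% and all three covariate coefficients
within ±0.10 across seeds), and the method-comparison study uses 20
seeds × 1,000 subjects (≈ 2 min). The cohort-scale simulation in
`analysis/01` uses the full 4,059 subjects. The test suite runs in
roughly ten minutes.

## What passing tests do and do not show

The synthetic generator emulates the covariate structure, sparse TDM
sampling and split rule of an ICU cohort, but real data differ in ways
the generator does not model: covariates drift over an ICU stay, renal
function changes within a day, assay error is not exactly the assumed
mixture, dosing records contain errors, and the true kinetics are not
exactly one-compartment. Passing the recovery and ordering suites shows
the estimators and the pipeline are correct and that the qualitative
method ranking emerges under plausible model misspecification — not
that the published numeric table would be reproduced on the original
(non-redistributable) records, whose headline metrics depend on that
specific extract.
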