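"""End-to-end synthetic benchmark of the four AUC24 predictors.

One call reproduces the study design on a virtual cohort: simulate a
sepsis cohort under the population model (optionally with generator-
vs-model misspecification), split it by the peak/trough rule, train the
random-forest ML and hybrid concentration models on the training half,
and score all four methods on the testing half against the trapezoidal
AUC24 from the measured pair.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .exposure import METHODS, run_benchmark
from .ml import LearnerSpec, build_feature_table
from .popmodel import PopulationModel
from .simulate import MisspecConfig, SamplingPolicy, simulate_cohort, split_train_test

__all__ = ["train_benchmark_models", "synthetic_benchmark",
           "parameter_recovery_study"]


def parameter_recovery_study(seed: int, n_subjects: int = 500):
    """Simulate-and-refit validation of the published population model.

    Simulates ``n_subjects`` virtual patients from the published fixed
    effects (cohort-table covariate distributions, 1000 mg q12h, six
    informative samples per subject, 30% CV lognormal IIV, combined
    residual error with 20% proportional CV and 1 mg/L additive SD, no
    generator misspecification) and refits the full nonlinear
    mixed-effects model with the Laplace fitter from neutral initials.

    Returns the :class:`vancoauc.estimation.PopulationFit`; recovery of
    theta_CL, theta_V and the three covariate coefficients is the
    headline check of the estimation stack.
    """
    from .estimation import FitConfig, ModelStructure, fit_population
    from .simulate import RegimenOption

    cohort = simulate_cohort(
        n_subjects,
        PopulationModel(),
        seed=seed,
        policy=SamplingPolicy.rich(6),
        misspec=MisspecConfig.off(),
        options=[RegimenOption(amount=1000.0, interval=12.0)],
    )
    return fit_population(cohort, ModelStructure.published(), FitConfig())


def train_benchmark_models(
    train_subjects,
    pop: PopulationModel,
    seed: int = 0,
    n_estimators: int = 500,
    pk_source: str = "typical",
) -> dict:
    """Fit the ML and hybrid random forests on a training cohort."""
    models = {}
    for mode in ("ml", "hybrid"):
        table = build_feature_table(train_subjects, mode=mode, pop=pop,
                                    pk_source=pk_source)
        est = LearnerSpec("random_forest",
                          {"n_estimators": n_estimators}).build(seed=seed)
        est.fit(table.X.to_numpy(dtype=float), table.y.to_numpy(dtype=float))
        models[mode] = est
    return models


def synthetic_benchmark(
    seed: int,
    pop: PopulationModel | None = None,
    n_subjects: int = 1000,
    misspec: MisspecConfig | None = None,
    policy: SamplingPolicy | None = None,
    methods: Sequence[str] = METHODS,
    n_estimators: int = 500,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate, split, train and score one virtual study replicate.

    Returns the per-method metric table and per-subject records (see
    :func:`vancoauc.exposure.run_benchmark`). The testing fraction is
    policy-driven; the default policy qualifies ~1.5% of subjects, so
    ``n_subjects`` should be large enough to leave a usable testing set.
    """
    pop = pop or PopulationModel()
    misspec = misspec if misspec is not None else MisspecConfig.default_on()
    policy = policy or SamplingPolicy()
    cohort = simulate_cohort(n_subjects, pop, seed=seed, policy=policy,
                             misspec=misspec)
    train, test = split_train_test(cohort)
    if not test:
        raise ValueError(
            "no subject qualified for the testing set; raise n_subjects or "
            "the policy's pair_prob"
        )
    models = train_benchmark_models(train, pop, seed=seed,
                                    n_estimators=n_estimators)
    return run_benchmark(test, pop, models, methods=methods)
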