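"""MAP forecasting, Laplace population fitting, stepwise search, bootstrap."""

import math
from dataclasses import replace

import numpy as np
import pytest

from vancoauc.estimation import (
    CovariateTerm,
    FitConfig,
    ModelStructure,
    SubjectData,
    bootstrap_validate,
    fit_population,
    laplace_ofv,
    map_estimate,
    stepwise_covariate_search,
)
from vancoauc.pk import ConcentrationPoint, PKParameters, Regimen, concentration_at
from vancoauc.popmodel import (
    Covariates,
    PopulationModel,
    ResidualModelType,
    VarianceComponents,
    typical_params,
)
from vancoauc.simulate import (
    CohortSpec,
    SamplingPolicy,
    assign_regimens,
    generate_cohort,
    simulate_cohort,
)

COV = Covariates(clcr=93, cci=5.62, wt=84)
REGIMEN = Regimen.intermittent(1000, 12, 1.0, 8)


def _subject(obs, cov=COV, regimen=REGIMEN, sid="s1"):
    return SubjectData(id=sid, regimen=regimen, observations=tuple(obs),
                       covariates=cov)


def _noise_free_subject(pop, eta=(-0.3, 0.2), n_obs=12):
    typ = typical_params(pop.fixed, COV)
    true = PKParameters(cl=typ.cl * math.exp(eta[0]), v=typ.v * math.exp(eta[1]))
    times = np.linspace(84.5, 95.5, n_obs)
    obs = [ConcentrationPoint(float(t), float(concentration_at(true, REGIMEN, t)))
           for t in times]
    return _subject(obs), true


class TestMapEstimate:
    def test_no_observations_returns_prior_mode(self, published_pop):
        res = map_estimate(_subject([]), published_pop)
        assert res.eta_hat.eta_cl == 0.0 and res.eta_hat.eta_v == 0.0
        assert res.params == typical_params(published_pop.fixed, COV)
        assert res.n_obs == 0

    def test_dense_noise_free_recovery(self):
        # with a small assumed residual variance, dense noise-free data pin
        # the individual parameters at truth
        pop = PopulationModel(
            variances=VarianceComponents(0.09, 0.09, 1e-6, 1e-6))
        subject, true = _noise_free_subject(pop)
        res = map_estimate(subject, pop)
        assert res.params.cl == pytest.approx(true.cl, rel=1e-3)
        assert res.params.v == pytest.approx(true.v, rel=1e-3)

    def test_matches_grid_search_single_observation(self, published_pop):
        typ = typical_params(published_pop.fixed, COV)
        subject = _subject([ConcentrationPoint(85.5, 30.0)])
        res = map_estimate(subject, published_pop)
        # coarse 101x101 grid oracle over eta in [-1, 1]^2
        from vancoauc.estimation import _Batch, _penalized_objective

        batch = _Batch([subject], ModelStructure(terms=(),
                                                 residual=published_pop.residual))
        grid = np.linspace(-1, 1, 101)
        E1, E2 = np.meshgrid(grid, grid, indexing="ij")
        etas = np.column_stack([E1.ravel(), E2.ravel()])
        best = None
        for e in etas.reshape(-1, 2):
            g = _penalized_objective(
                batch, e[None, :], np.array([math.log(typ.cl)]),
                np.array([math.log(typ.v)]), np.array([0.09, 0.09]),
                published_pop.variances.delta2_prop,
                published_pop.variances.delta2_add, published_pop.residual)[0]
            if best is None or g < best[0]:
                best = (g, e)
        step = grid[1] - grid[0]
        assert abs(res.eta_hat.eta_cl - best[1][0]) <= step
        assert abs(res.eta_hat.eta_v - best[1][1]) <= step
        assert res.objective <= best[0] + 1e-9

    def test_shrinkage_limits(self, published_pop):
        # omega^2 -> 0 pins the estimate at the typical values; omega^2 -> inf
        # releases it to the individual least-squares fit
        subject, true = _noise_free_subject(published_pop)
        typ = typical_params(published_pop.fixed, COV)
        tight = PopulationModel(variances=VarianceComponents(1e-10, 1e-10, 0.04, 1.0))
        res = map_estimate(subject, tight)
        assert res.params.cl == pytest.approx(typ.cl, rel=1e-3)
        assert res.params.v == pytest.approx(typ.v, rel=1e-3)
        loose = PopulationModel(variances=VarianceComponents(1e4, 1e4, 1e-6, 1e-6))
        res = map_estimate(subject, loose)
        assert res.params.cl == pytest.approx(true.cl, rel=1e-3)
        assert res.params.v == pytest.approx(true.v, rel=1e-3)

    def test_requires_positive_omega(self):
        pop = PopulationModel(variances=VarianceComponents(0.0, 0.09, 0.04, 1.0))
        with pytest.raises(ValueError):
            map_estimate(_subject([ConcentrationPoint(85.0, 20.0)]), pop)


class TestLaplaceMarginal:
    def _gh_ofv(self, pop, subject, t_obs, y, order=120):
        """Gauss-Hermite quadrature oracle (prior-weighted) for a
        one-observation subject with additive error.

        The concentration is evaluated with an explicit superposition
        formula written here, independent of the package implementation.
        """
        typ = typical_params(pop.fixed, COV)
        nodes, weights = np.polynomial.hermite_e.hermegauss(order)
        om = math.sqrt(pop.variances.omega2_cl)
        sd = math.sqrt(pop.variances.delta2_add)
        cl = typ.cl * np.exp(om * nodes)[:, None]  # (order, 1)
        v = typ.v * np.exp(om * nodes)[None, :]  # (1, order)
        k = cl / v
        f = np.zeros_like(k)
        for ev in subject.regimen.events:
            el = t_obs - ev.start
            if el <= 0:
                continue
            te = min(el, ev.duration)
            f += (ev.rate / cl) * (1 - np.exp(-k * te)) * np.exp(-k * (el - te))
        lik = np.exp(-0.5 * ((y - f) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
        total = weights @ lik @ weights
        return -2.0 * math.log(total / (2 * math.pi))

    def test_matches_quadrature_single_subject(self):
        # small IIV keeps the eta-posterior near-Gaussian, the regime in
        # which the Laplace approximation is accurate to the quadrature
        # truth within 1e-3
        pop = PopulationModel(
            variances=VarianceComponents(0.001, 0.001, 0.0, 1.0),
            residual=ResidualModelType.ADDITIVE,
        )
        subject = _subject([ConcentrationPoint(86.0, 28.0)])
        approx = laplace_ofv([subject], pop)
        assert approx == pytest.approx(self._gh_ofv(pop, subject, 86.0, 28.0), abs=1e-3)

    def test_quadrature_gap_grows_gracefully_with_iiv(self):
        # at 20% CV the same comparison shows the expected O(omega^2)
        # approximation error, still small on the -2logL scale
        pop = PopulationModel(
            variances=VarianceComponents(0.04, 0.04, 0.0, 1.0),
            residual=ResidualModelType.ADDITIVE,
        )
        subject = _subject([ConcentrationPoint(86.0, 28.0)])
        approx = laplace_ofv([subject], pop)
        assert approx == pytest.approx(self._gh_ofv(pop, subject, 86.0, 28.0), abs=0.05)


class TestFitPopulation:
    def test_parameter_recovery_small_cohort(self, published_pop):
        # 150 subjects, informative sampling: fixed effects within 15%,
        # exponents within 0.15 (tighter checks at n=500 live in the
        # acceptance suite)
        cohort = simulate_cohort(150, published_pop, seed=21,
                                 policy=SamplingPolicy.rich(6))
        fit = fit_population(cohort, ModelStructure.published(), FitConfig())
        assert fit.converged
        assert fit.theta_cl == pytest.approx(3.35, rel=0.15)
        assert fit.theta_v == pytest.approx(98.5, rel=0.15)
        betas = {(t.param, t.cov): b for t, b in fit.betas.items()}
        assert betas[("cl", "clcr")] == pytest.approx(0.997, abs=0.15)

    def test_degenerate_iiv_recovers_theta(self, published_pop):
        # all eta = 0 in the generator; fit with omega^2 pinned near zero
        pop = PopulationModel(variances=VarianceComponents(0.0, 0.0, 0.01, 0.25))
        cohort = simulate_cohort(100, pop, seed=22, policy=SamplingPolicy.rich(6))
        fit = fit_population(
            cohort, ModelStructure.published(),
            FitConfig(fix_omega2=1e-6, delta2_prop0=0.01, delta2_add0=0.25),
        )
        assert fit.theta_cl == pytest.approx(3.35, rel=0.02)
        assert fit.theta_v == pytest.approx(98.5, rel=0.02)

    def test_needs_at_least_two_subjects(self, published_pop):
        with pytest.raises(ValueError):
            fit_population([_subject([ConcentrationPoint(85.0, 20.0)])])


class TestStepwise:
    @pytest.fixture(scope="class")
    def small_cohort(self, published_pop):
        return simulate_cohort(80, published_pop, seed=30,
                               policy=SamplingPolicy.rich(4))

    def test_empty_candidates_return_base(self, small_cohort):
        res = stepwise_covariate_search(small_cohort, [], base=ModelStructure.base())
        assert res.structure == ModelStructure.base()
        assert res.path == ()

    def test_infinite_threshold_adds_nothing(self, small_cohort):
        cand = [CovariateTerm("cl", "clcr", "power", 93.0)]
        res = stepwise_covariate_search(small_cohort, cand,
                                        add_threshold=math.inf,
                                        base=ModelStructure.base())
        assert res.structure.terms == ()

    def test_true_covariate_in_null_covariate_out(self, small_cohort):
        # CLCR drives CL in the generator; hemoglobin does not
        cand = [CovariateTerm("cl", "clcr", "power", 93.0),
                CovariateTerm("cl", "hgb", "power", 9.51)]
        res = stepwise_covariate_search(small_cohort, cand,
                                        base=ModelStructure.base())
        names = {t.cov for t in res.structure.terms}
        assert "clcr" in names
        assert "hgb" not in names


class TestBootstrap:
    @pytest.fixture(scope="class")
    def tiny_fit(self):
        # well-specified single-covariate problem: the generator's only
        # covariate effect is CLCR on CL, matching the fitted structure
        from vancoauc.popmodel import FixedEffects

        pop = PopulationModel(fixed=FixedEffects(beta_cci=0.0, beta_wt=0.0))
        cohort = simulate_cohort(50, pop, seed=41, policy=SamplingPolicy.rich(4))
        structure = ModelStructure(
            terms=(CovariateTerm("cl", "clcr", "power", 93.0),))
        fit = fit_population(cohort, structure, FitConfig(maxiter=100))
        return cohort, structure, fit

    def test_deterministic_resamples(self, tiny_fit):
        cohort, structure, fit = tiny_fit
        a = bootstrap_validate(cohort, structure, n_reps=3, seed=5,
                               reference=fit, config=FitConfig(maxiter=20))
        b = bootstrap_validate(cohort, structure, n_reps=3, seed=5,
                               reference=fit, config=FitConfig(maxiter=20))
        assert np.allclose(a[["median", "ci_lo", "ci_hi"]],
                           b[["median", "ci_lo", "ci_hi"]])

    def test_single_rep_collapses_ci(self, tiny_fit):
        cohort, structure, fit = tiny_fit
        with pytest.warns(UserWarning):
            out = bootstrap_validate(cohort, structure, n_reps=1, seed=6,
                                     reference=fit, config=FitConfig(maxiter=20))
        assert np.allclose(out["ci_lo"], out["ci_hi"])
        assert np.allclose(out["median"], out["ci_lo"])

    def test_truth_inside_bootstrap_ci(self, tiny_fit):
        cohort, structure, fit = tiny_fit
        out = bootstrap_validate(cohort, structure, n_reps=50, seed=7,
                                 reference=fit, config=FitConfig(maxiter=40))
        assert out.attrs["n_failed"] <= 5
        # generating values for the parameters of this structure
        assert out.loc["theta_cl", "ci_lo"] <= 3.35 <= out.loc["theta_cl", "ci_hi"]
        assert out.loc["theta_v", "ci_lo"] <= 98.5 <= out.loc["theta_v", "ci_hi"]
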