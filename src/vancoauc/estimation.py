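"""Nonlinear mixed-effects estimation and MAP-Bayesian forecasting.

Implements the population side of the workflow:

* ``map_estimate`` — posterior-mode (MAP) estimation of one subject's
  random effects given a population prior, the engine behind Bayesian
  AUC24 forecasting in therapeutic drug monitoring.
* ``fit_population`` — marginal maximum likelihood for the nonlinear
  mixed-effects model via the Laplace approximation: an inner Newton
  solve for each subject's posterior mode and a quasi-Newton outer
  search over fixed effects, covariate coefficients and variance
  components.
* ``stepwise_covariate_search`` — forward-inclusion / backward-
  elimination covariate screening on the likelihood-ratio (delta-OFV)
  scale.
* ``bootstrap_validate`` — nonparametric bootstrap (resampling subjects)
  for parameter medians and percentile confidence intervals.

The subject-level model is two-dimensional (eta on CL and V), so the
inner problem is solved by a damped Newton iteration with
finite-difference derivatives, vectorised across all subjects at once.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .pk import ConcentrationPoint, PKParameters, Regimen
from .popmodel import (
    Covariates,
    FixedEffects,
    PopulationModel,
    RandomEffects,
    ResidualModelType,
    VarianceComponents,
    individual_params,
)

__all__ = [
    "SubjectData",
    "MapResult",
    "PopulationFit",
    "CovariateTerm",
    "ModelStructure",
    "FitConfig",
    "map_estimate",
    "fit_population",
    "stepwise_covariate_search",
    "bootstrap_validate",
]

_VAR_FLOOR = 1e-8  # lower bound for variance components (log-scale fit)
_DET_FLOOR = 1e-8  # floor on det(Hessian/2) in the Laplace log-determinant
_INNER_TOL = 1e-6  # gradient-norm tolerance, inner Newton on eta
_OUTER_TOL = 1e-5  # gradient tolerance, outer quasi-Newton


@dataclass(frozen=True)
class SubjectData:
    """One patient: dosing history, concentration samples, covariates.

    ``truth`` optionally carries simulation ground truth (true eta, CL,
    V, AUC24) for validation; it is never read by any estimator.
    """

    id: str
    regimen: Regimen
    observations: tuple[ConcentrationPoint, ...]
    covariates: Covariates
    truth: dict | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))
        if self.regimen.events:
            first = self.regimen.events[0].start
            if any(o.time < first for o in self.observations):
                raise ValueError(
                    f"subject {self.id}: observation precedes first dose"
                )

    @property
    def obs_times(self) -> np.ndarray:
        return np.array([o.time for o in self.observations], dtype=float)

    @property
    def obs_values(self) -> np.ndarray:
        return np.array([o.value for o in self.observations], dtype=float)


@dataclass(frozen=True)
class MapResult:
    """MAP estimate of one subject's random effects and PK parameters."""

    eta_hat: RandomEffects
    params: PKParameters
    objective: float
    n_obs: int


@dataclass(frozen=True)
class CovariateTerm:
    """One covariate-parameter relation.

    ``form='power'`` contributes (cov/ref)^beta, ``form='exponential'``
    contributes exp(beta * cov/ref); both are linear in beta on the log
    scale, which the fitter exploits.
    """

    param: str  # 'cl' or 'v'
    cov: str  # attribute name on Covariates
    form: str  # 'power' or 'exponential'
    ref: float

    def __post_init__(self) -> None:
        if self.param not in ("cl", "v"):
            raise ValueError("param must be 'cl' or 'v'")
        if self.form not in ("power", "exponential"):
            raise ValueError("form must be 'power' or 'exponential'")
        if self.ref <= 0:
            raise ValueError("reference value must be > 0")

    def design_value(self, cov: Covariates) -> float:
        x = getattr(cov, self.cov) / self.ref
        return math.log(x) if self.form == "power" else x


@dataclass(frozen=True)
class ModelStructure:
    """Structural + covariate-model choice handed to the fitter."""

    terms: tuple[CovariateTerm, ...] = ()
    residual: ResidualModelType = ResidualModelType.COMBINED

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))

    @classmethod
    def published(cls) -> "ModelStructure":
        """The final published covariate structure: CLCR and CCI on CL, WT on V."""
        return cls(
            terms=(
                CovariateTerm("cl", "clcr", "power", 93.0),
                CovariateTerm("cl", "cci", "exponential", 5.62),
                CovariateTerm("v", "wt", "power", 84.0),
            )
        )

    @classmethod
    def base(cls, residual: ResidualModelType = ResidualModelType.COMBINED) -> "ModelStructure":
        return cls(terms=(), residual=residual)

    def with_term(self, term: CovariateTerm) -> "ModelStructure":
        return replace(self, terms=self.terms + (term,))

    def without_term(self, term: CovariateTerm) -> "ModelStructure":
        return replace(self, terms=tuple(t for t in self.terms if t != term))


@dataclass(frozen=True)
class FitConfig:
    """Initial values, bounds and optimizer settings for ``fit_population``."""

    theta_cl0: float = 4.0
    theta_v0: float = 70.0
    beta0: float = 0.0
    omega2_0: float = 0.09
    delta2_prop0: float = 0.04
    delta2_add0: float = 1.0
    fix_omega2: float | None = None  # fit with omega^2 pinned (degenerate checks)
    maxiter: int = 200

    def initial_vector(self, structure: ModelStructure) -> np.ndarray:
        p = [math.log(self.theta_cl0), math.log(self.theta_v0)]
        p += [self.beta0] * len(structure.terms)
        if self.fix_omega2 is None:
            p += [math.log(self.omega2_0)] * 2
        if structure.residual in (
            ResidualModelType.PROPORTIONAL,
            ResidualModelType.COMBINED,
            ResidualModelType.EXPONENTIAL,
        ):
            p.append(math.log(self.delta2_prop0))
        if structure.residual in (ResidualModelType.ADDITIVE, ResidualModelType.COMBINED):
            p.append(math.log(self.delta2_add0))
        return np.array(p, dtype=float)


@dataclass(frozen=True)
class PopulationFit:
    """Result of a population fit."""

    structure: ModelStructure
    theta_cl: float
    theta_v: float
    betas: dict
    omega2_cl: float
    omega2_v: float
    delta2_prop: float
    delta2_add: float
    ofv: float
    converged: bool
    n_subjects: int
    n_obs: int

    def to_population_model(self) -> PopulationModel:
        """Express the fit as a :class:`PopulationModel` document.

        Only valid when every covariate term maps onto a field of the
        published covariate structure (clcr/cci on CL, wt on V);
        unmapped terms raise.
        """
        known = {
            ("cl", "clcr"): "beta_clcr",
            ("cl", "cci"): "beta_cci",
            ("v", "wt"): "beta_wt",
        }
        kwargs = {"theta_cl": self.theta_cl, "theta_v": self.theta_v,
                  "beta_clcr": 0.0, "beta_cci": 0.0, "beta_wt": 0.0}
        for term, beta in self.betas.items():
            key = (term.param, term.cov)
            if key not in known:
                raise ValueError(f"term {term} has no slot in PopulationModel")
            kwargs[known[key]] = beta
        refs = {t.cov: t.ref for t in self.betas}
        kwargs["ref_clcr"] = refs.get("clcr", 93.0)
        kwargs["ref_cci"] = refs.get("cci", 5.62)
        kwargs["ref_wt"] = refs.get("wt", 84.0)
        return PopulationModel(
            fixed=FixedEffects(**kwargs),
            variances=VarianceComponents(
                omega2_cl=self.omega2_cl,
                omega2_v=self.omega2_v,
                delta2_prop=self.delta2_prop,
                delta2_add=self.delta2_add,
            ),
            residual=self.structure.residual,
        )


# ----------------------------------------------------------------------
# batched computation engine
# ----------------------------------------------------------------------

class _Batch:
    """Padded array view of a cohort for vectorised likelihood evaluation."""

    def __init__(self, subjects: Sequence[SubjectData], structure: ModelStructure):
        self.subjects = list(subjects)
        self.structure = structure
        S = len(self.subjects)
        t_max = max((len(s.observations) for s in self.subjects), default=0)
        d_max = max((len(s.regimen.events) for s in self.subjects), default=0)
        self.obs_t = np.zeros((S, t_max))
        self.obs_y = np.zeros((S, t_max))
        self.mask = np.zeros((S, t_max), dtype=bool)
        self.dose_start = np.full((S, d_max), np.inf)
        self.dose_rate = np.zeros((S, d_max))
        self.dose_dur = np.ones((S, d_max))
        for i, s in enumerate(self.subjects):
            n = len(s.observations)
            self.obs_t[i, :n] = s.obs_times
            self.obs_y[i, :n] = s.obs_values
            self.mask[i, :n] = True
            for j, ev in enumerate(s.regimen.events):
                self.dose_start[i, j] = ev.start
                self.dose_rate[i, j] = ev.rate
                self.dose_dur[i, j] = ev.duration
        self.n_obs = self.mask.sum()
        self.n_obs_per_subj = self.mask.sum(axis=1)
        # design matrices for log CL / log V covariate models
        cl_terms = [t for t in structure.terms if t.param == "cl"]
        v_terms = [t for t in structure.terms if t.param == "v"]
        self.cl_terms, self.v_terms = cl_terms, v_terms
        self.X_cl = np.array(
            [[t.design_value(s.covariates) for t in cl_terms] for s in self.subjects]
        ).reshape(S, len(cl_terms))
        self.X_v = np.array(
            [[t.design_value(s.covariates) for t in v_terms] for s in self.subjects]
        ).reshape(S, len(v_terms))

    def conc(self, cl: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Predicted concentration matrix (S, Tmax) for per-subject CL, V."""
        return self.conc_multi(cl[:, None], v[:, None])[:, 0, :]

    def conc_multi(self, cl: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Concentrations (S, P, Tmax) for P parameter points per subject.

        Evaluating a whole finite-difference stencil in one tensor
        operation is what keeps the inner Newton solve cheap.
        """
        k = (cl / v)[:, :, None, None]  # (S, P, 1, 1)
        elapsed = (self.obs_t[:, None, :, None]
                   - self.dose_start[:, None, None, :])  # (S, 1, T, D)
        te = np.minimum(np.maximum(elapsed, 0.0), self.dose_dur[:, None, None, :])
        pos = elapsed > 0.0
        with np.errstate(over="ignore", invalid="ignore"):
            c = (
                (self.dose_rate[:, None, None, :] / cl[:, :, None, None])
                * (1.0 - np.exp(-k * te))
                * np.exp(-k * np.where(pos, elapsed - te, 0.0))
            )
        return np.where(pos, c, 0.0).sum(axis=3)


def _outer_bounds(structure: ModelStructure, config: FitConfig) -> list[tuple]:
    """Box bounds for the outer search (log scale for positive quantities)."""
    b = [(math.log(0.05), math.log(100.0)),  # ln theta_cl, L/h
         (math.log(5.0), math.log(2000.0))]  # ln theta_v, L
    b += [(-5.0, 5.0)] * len(structure.terms)
    n_var = len(config.initial_vector(structure)) - len(b)
    # IIV variance up to 10 (>300% CV) and residual variances up to 1e3
    # cover anything pharmacologically meaningful
    if config.fix_omega2 is None:
        b += [(math.log(_VAR_FLOOR), math.log(10.0))] * 2
        n_var -= 2
    b += [(math.log(_VAR_FLOOR), math.log(1e3))] * n_var
    return b


def _unpack(p: np.ndarray, structure: ModelStructure, config: FitConfig) -> dict:
    """Decode the outer optimizer's parameter vector."""
    p = np.clip(np.asarray(p, dtype=float), -60.0, 60.0)
    i = 0
    out = {"theta_cl": math.exp(p[i]), "theta_v": math.exp(p[i + 1])}
    i += 2
    nb = len(structure.terms)
    out["betas"] = np.asarray(p[i : i + nb], dtype=float)
    i += nb
    if config.fix_omega2 is None:
        out["omega2"] = np.exp(p[i : i + 2])
        i += 2
    else:
        out["omega2"] = np.array([config.fix_omega2, config.fix_omega2])
    res = structure.residual
    if res in (ResidualModelType.PROPORTIONAL, ResidualModelType.COMBINED,
               ResidualModelType.EXPONENTIAL):
        out["delta2_prop"] = math.exp(p[i])
        i += 1
    else:
        out["delta2_prop"] = 0.0
    if res in (ResidualModelType.ADDITIVE, ResidualModelType.COMBINED):
        out["delta2_add"] = math.exp(p[i])
        i += 1
    else:
        out["delta2_add"] = 0.0
    return out


def _penalized_objective_multi(
    batch: _Batch,
    eta: np.ndarray,  # (S, P, 2)
    log_cl_typ: np.ndarray,
    log_v_typ: np.ndarray,
    omega2: np.ndarray,
    delta2_prop: float,
    delta2_add: float,
    residual: ResidualModelType,
) -> np.ndarray:
    """Per-subject penalized -2 log joint (up to constants): the MAP objective

    g(eta) = sum_j [ ln v_j + (y_j - f_j)^2 / v_j ] + eta' diag(1/omega2) eta

    evaluated at P eta-points per subject at once; returns (S, P).
    """
    eta = np.clip(eta, -30.0, 30.0)
    cl = np.exp(log_cl_typ[:, None] + eta[:, :, 0])
    v = np.exp(log_v_typ[:, None] + eta[:, :, 1])
    f = batch.conc_multi(cl, v)  # (S, P, T)
    mask = batch.mask[:, None, :]
    obs = batch.obs_y[:, None, :]
    if residual is ResidualModelType.EXPONENTIAL:
        # fit on the log scale: ln y = ln f + eps
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(mask, np.log(np.maximum(obs, 1e-12))
                         - np.log(np.maximum(f, 1e-12)), 0.0)
        var = np.full_like(f, max(delta2_prop, _VAR_FLOOR))
    else:
        r = np.where(mask, obs - f, 0.0)
        var = np.maximum(delta2_prop * np.square(f) + delta2_add, _VAR_FLOOR)
    ll = np.where(mask, np.log(var) + np.square(r) / var, 0.0).sum(axis=2)
    pen = (np.square(eta[:, :, 0]) / omega2[0]
           + np.square(eta[:, :, 1]) / omega2[1])
    return ll + pen


def _penalized_objective(batch, eta, log_cl_typ, log_v_typ, omega2,
                         delta2_prop, delta2_add, residual) -> np.ndarray:
    """Single eta-point per subject; returns (S,)."""
    return _penalized_objective_multi(
        batch, eta[:, None, :], log_cl_typ, log_v_typ, omega2,
        delta2_prop, delta2_add, residual,
    )[:, 0]


def _inner_newton(
    batch: _Batch,
    log_cl_typ: np.ndarray,
    log_v_typ: np.ndarray,
    omega2: np.ndarray,
    delta2_prop: float,
    delta2_add: float,
    residual: ResidualModelType,
    eta0: np.ndarray,
    tol: float = _INNER_TOL,
    max_iter: int = 60,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Damped Newton minimisation of g(eta) for every subject at once.

    Returns (eta_hat, g_min, hessians) where ``hessians`` is the (S,2,2)
    finite-difference Hessian of g at the optimum (used by the Laplace
    log-determinant correction).
    """
    S = len(batch.subjects)
    eta = eta0.copy()
    h = 1e-4
    # 9-point stencil offsets: center, +/- axes, corners
    stencil = h * np.array([
        [0, 0], [1, 0], [-1, 0], [0, 1], [0, -1],
        [1, 1], [1, -1], [-1, 1], [-1, -1],
    ], dtype=float)  # (9, 2)

    def g(e: np.ndarray) -> np.ndarray:
        return _penalized_objective(
            batch, e, log_cl_typ, log_v_typ, omega2, delta2_prop, delta2_add, residual
        )

    def derivatives(e: np.ndarray):
        pts = e[:, None, :] + stencil[None, :, :]  # (S, 9, 2)
        gs = _penalized_objective_multi(
            batch, pts, log_cl_typ, log_v_typ, omega2,
            delta2_prop, delta2_add, residual,
        )  # (S, 9)
        g0 = gs[:, 0]
        grad = np.stack([
            (gs[:, 1] - gs[:, 2]) / (2 * h),
            (gs[:, 3] - gs[:, 4]) / (2 * h),
        ], axis=1)
        H = np.empty((S, 2, 2))
        H[:, 0, 0] = (gs[:, 1] - 2 * g0 + gs[:, 2]) / h**2
        H[:, 1, 1] = (gs[:, 3] - 2 * g0 + gs[:, 4]) / h**2
        H[:, 0, 1] = H[:, 1, 0] = (gs[:, 5] - gs[:, 6] - gs[:, 7] + gs[:, 8]) / (4 * h**2)
        return g0, grad, H

    active = np.ones(S, dtype=bool)
    g0, grad, H = derivatives(eta)
    for _ in range(max_iter):
        gn = np.abs(grad).max(axis=1)
        active = gn > tol
        if not active.any():
            break
        # make Hessian positive definite per subject (Levenberg shift)
        Hpd = H.copy()
        tr = Hpd[:, 0, 0] + Hpd[:, 1, 1]
        det = Hpd[:, 0, 0] * Hpd[:, 1, 1] - Hpd[:, 0, 1] ** 2
        lam_min = 0.5 * (tr - np.sqrt(np.maximum(tr**2 - 4 * det, 0.0)))
        # proportional Levenberg shift: an indefinite or ill-conditioned
        # Hessian gets a well-conditioned surrogate, not a near-singular one
        shift = np.maximum(1e-3 + 0.2 * np.abs(lam_min) - lam_min, 0.0)
        Hpd[:, 0, 0] += shift
        Hpd[:, 1, 1] += shift
        det = Hpd[:, 0, 0] * Hpd[:, 1, 1] - Hpd[:, 0, 1] ** 2
        step = np.empty_like(grad)
        with np.errstate(divide="ignore", invalid="ignore"):
            step[:, 0] = -(Hpd[:, 1, 1] * grad[:, 0] - Hpd[:, 0, 1] * grad[:, 1]) / det
            step[:, 1] = -(Hpd[:, 0, 0] * grad[:, 1] - Hpd[:, 0, 1] * grad[:, 0]) / det
        # flat or degenerate curvature: fall back to steepest descent
        bad = ~np.isfinite(step).all(axis=1) | (det <= 1e-12)
        step[bad] = -grad[bad]
        # trust region on the lognormal scale: rescale (never clip
        # element-wise, which would corrupt the descent direction)
        norm = np.abs(step).max(axis=1)
        factor = np.where(norm > 2.0, 2.0 / np.maximum(norm, 1e-300), 1.0)
        step *= factor[:, None]
        # per-subject backtracking line search (NaN trial counts as worse)
        scale = np.where(active, 1.0, 0.0)
        for _bt in range(12):
            trial = eta + scale[:, None] * step
            g_trial = g(trial)
            worse = active & ~(g_trial <= g0 + 1e-12)
            if not worse.any():
                break
            scale = np.where(worse, scale * 0.5, scale)
        else:
            scale = np.where(worse, 0.0, scale)  # no descent found: stay put
        eta = eta + scale[:, None] * step
        g0, grad, H = derivatives(eta)
    return eta, g0, H


def _laplace_ofv(batch: _Batch, p: np.ndarray, config: FitConfig) -> float:
    """Laplace-approximated -2 log marginal likelihood of the whole cohort."""
    u = _unpack(p, batch.structure, config)
    log_cl = math.log(u["theta_cl"]) + batch.X_cl @ u["betas"][: len(batch.cl_terms)] \
        if batch.cl_terms else np.full(len(batch.subjects), math.log(u["theta_cl"]))
    betas_v = u["betas"][len(batch.cl_terms):]
    log_v = math.log(u["theta_v"]) + batch.X_v @ betas_v \
        if batch.v_terms else np.full(len(batch.subjects), math.log(u["theta_v"]))
    omega2 = np.maximum(u["omega2"], _VAR_FLOOR)
    # inner solve always starts at the prior mode: the objective must be a
    # pure function of p for the outer line search to be reliable
    eta, gmin, H = _inner_newton(
        batch, log_cl, log_v, omega2, u["delta2_prop"], u["delta2_add"],
        batch.structure.residual, np.zeros((len(batch.subjects), 2)),
    )
    Hh = H / 2.0
    det = Hh[:, 0, 0] * Hh[:, 1, 1] - Hh[:, 0, 1] ** 2
    # a (near-)singular Hessian means the posterior is flat in some
    # direction; flooring the determinant keeps the approximation from
    # rewarding degenerate variance configurations
    det = np.maximum(det, _DET_FLOOR)
    ofv = (
        gmin.sum()
        + batch.n_obs * math.log(2 * math.pi)
        + len(batch.subjects) * float(np.log(omega2).sum())
        + float(np.log(det).sum())
    )
    if not np.isfinite(ofv):
        return 1e12
    return float(ofv)


# ----------------------------------------------------------------------
# public estimators
# ----------------------------------------------------------------------

def map_estimate(subject: SubjectData, pop: PopulationModel) -> MapResult:
    """MAP-Bayesian estimate of one subject's random effects.

    Minimises over eta the penalized objective

        sum_j [ (y_j - f_j(eta))^2 / var_j(eta) + ln var_j(eta) ]
          + eta_cl^2/omega2_cl + eta_v^2/omega2_v

    where f is the one-compartment infusion model at the individual
    parameters and var the residual-error variance. With no observations
    the prior mode eta = 0 (typical values) is returned directly.
    """
    if pop.variances.omega2_cl <= 0 or pop.variances.omega2_v <= 0:
        raise ValueError("MAP estimation requires positive omega^2")
    from .popmodel import typical_params

    typ = typical_params(pop.fixed, subject.covariates)
    if len(subject.observations) == 0:
        return MapResult(
            eta_hat=RandomEffects(0.0, 0.0), params=typ, objective=0.0, n_obs=0
        )
    structure = ModelStructure(terms=(), residual=pop.residual)
    batch = _Batch([subject], structure)
    omega2 = np.array([pop.variances.omega2_cl, pop.variances.omega2_v])
    log_cl = np.array([math.log(typ.cl)])
    log_v = np.array([math.log(typ.v)])
    eta, gmin, _H = _inner_newton(
        batch, log_cl, log_v, omega2,
        pop.variances.delta2_prop, pop.variances.delta2_add, pop.residual,
        np.zeros((1, 2)),
    )
    if not np.isfinite(gmin[0]):
        raise RuntimeError("MAP objective non-finite at the optimum")
    eta_hat = RandomEffects(float(eta[0, 0]), float(eta[0, 1]))
    params = individual_params(pop.fixed, subject.covariates, eta_hat)
    return MapResult(eta_hat=eta_hat, params=params, objective=float(gmin[0]),
                     n_obs=len(subject.observations))


def fit_population(
    dataset: Sequence[SubjectData],
    structure: ModelStructure | None = None,
    config: FitConfig | None = None,
) -> PopulationFit:
    """Fit the nonlinear mixed-effects model by Laplace marginal likelihood.

    Inner problem: per-subject MAP (Newton); outer problem: L-BFGS-B over
    log typical values, covariate coefficients and log variance
    components. Non-convergence is reported through the ``converged``
    flag rather than raised.
    """
    structure = structure or ModelStructure.published()
    config = config or FitConfig()
    subjects = [s for s in dataset if len(s.observations) > 0]
    if len(subjects) < 2:
        raise ValueError("population fitting needs at least 2 subjects with data")
    batch = _Batch(subjects, structure)
    p0 = config.initial_vector(structure)
    bounds = _outer_bounds(structure, config)
    opts = {"maxiter": config.maxiter, "gtol": _OUTER_TOL, "eps": 1e-5}

    def objective(p: np.ndarray) -> float:
        return _laplace_ofv(batch, p, config)

    # stage 1: typical values and covariate coefficients at the initial
    # variance components (the structural fit is well conditioned and keeps
    # the variance search from wandering into degenerate corners)
    n_struct = 2 + len(structure.terms)
    p1 = p0.copy()
    if len(p0) > n_struct:
        def stage1(q: np.ndarray) -> float:
            p = p0.copy()
            p[:n_struct] = q
            return _laplace_ofv(batch, p, config)

        res1 = optimize.minimize(stage1, p0[:n_struct], method="L-BFGS-B",
                                 bounds=bounds[:n_struct], options=opts)
        p1[:n_struct] = res1.x
    # stage 2: everything jointly
    res = optimize.minimize(objective, p1, method="L-BFGS-B", bounds=bounds,
                            options=opts)
    u = _unpack(res.x, structure, config)
    betas = {t: float(b) for t, b in zip(structure.terms, u["betas"])}
    return PopulationFit(
        structure=structure,
        theta_cl=u["theta_cl"],
        theta_v=u["theta_v"],
        betas=betas,
        omega2_cl=float(u["omega2"][0]),
        omega2_v=float(u["omega2"][1]),
        delta2_prop=u["delta2_prop"],
        delta2_add=u["delta2_add"],
        ofv=float(res.fun),
        converged=bool(res.success),
        n_subjects=len(subjects),
        n_obs=int(batch.n_obs),
    )


def laplace_ofv(
    dataset: Sequence[SubjectData],
    pop: PopulationModel,
    structure: ModelStructure | None = None,
) -> float:
    """-2 log marginal likelihood of a cohort at fixed model parameters.

    Exposed for oracle checks (e.g. against numerical quadrature over the
    random effects on one-subject problems).
    """
    structure = structure or ModelStructure(terms=(), residual=pop.residual)
    batch = _Batch(list(dataset), structure)
    from .popmodel import typical_params

    log_cl = np.array([math.log(typical_params(pop.fixed, s.covariates).cl)
                       for s in batch.subjects])
    log_v = np.array([math.log(typical_params(pop.fixed, s.covariates).v)
                      for s in batch.subjects])
    omega2 = np.array([pop.variances.omega2_cl, pop.variances.omega2_v])
    eta, gmin, H = _inner_newton(
        batch, log_cl, log_v, omega2,
        pop.variances.delta2_prop, pop.variances.delta2_add, pop.residual,
        np.zeros((len(batch.subjects), 2)),
    )
    Hh = H / 2.0
    det = np.maximum(Hh[:, 0, 0] * Hh[:, 1, 1] - Hh[:, 0, 1] ** 2, _DET_FLOOR)
    return float(
        gmin.sum()
        + batch.n_obs * math.log(2 * math.pi)
        + len(batch.subjects) * float(np.log(omega2).sum())
        + float(np.log(det).sum())
    )


@dataclass(frozen=True)
class StepwiseResult:
    structure: ModelStructure
    path: tuple[dict, ...]  # inclusion/elimination log


def stepwise_covariate_search(
    dataset: Sequence[SubjectData],
    candidates: Sequence[CovariateTerm],
    add_threshold: float = 3.84,
    remove_threshold: float = 6.63,
    base: ModelStructure | None = None,
    config: FitConfig | None = None,
) -> StepwiseResult:
    """Forward-inclusion / backward-elimination covariate screening.

    A candidate enters when it lowers the OFV by at least
    ``add_threshold`` (chi^2_1 at 0.05 by default) and survives backward
    elimination only if removing it would raise the OFV by at least
    ``remove_threshold`` (chi^2_1 at 0.01). Largest delta-OFV first; ties
    broken by candidate order.
    """
    base = base or ModelStructure.base()
    config = config or FitConfig()
    current = base
    remaining = list(candidates)
    path: list[dict] = []
    ofv = fit_population(dataset, current, config).ofv

    # forward inclusion
    while remaining:
        deltas = []
        for term in remaining:
            trial_fit = fit_population(dataset, current.with_term(term), config)
            deltas.append((ofv - trial_fit.ofv, term, trial_fit.ofv))
        deltas.sort(key=lambda x: -x[0])
        best_delta, best_term, best_ofv = deltas[0]
        if best_delta < add_threshold:
            break
        current = current.with_term(best_term)
        remaining.remove(best_term)
        path.append({"step": "add", "term": best_term, "delta_ofv": best_delta})
        ofv = best_ofv

    # backward elimination
    removable = [t for t in current.terms if t not in base.terms]
    changed = True
    while changed and removable:
        changed = False
        deltas = []
        for term in removable:
            trial_fit = fit_population(dataset, current.without_term(term), config)
            deltas.append((trial_fit.ofv - ofv, term, trial_fit.ofv))
        deltas.sort(key=lambda x: x[0])
        worst_delta, worst_term, worst_ofv = deltas[0]
        if worst_delta < remove_threshold:
            current = current.without_term(worst_term)
            removable.remove(worst_term)
            path.append({"step": "remove", "term": worst_term, "delta_ofv": worst_delta})
            ofv = worst_ofv
            changed = True
    return StepwiseResult(structure=current, path=tuple(path))


def bootstrap_validate(
    dataset: Sequence[SubjectData],
    structure: ModelStructure | None = None,
    n_reps: int = 200,
    seed: int = 0,
    config: FitConfig | None = None,
    reference: PopulationFit | None = None,
) -> pd.DataFrame:
    """Nonparametric bootstrap of the population fit.

    Resamples subjects with replacement ``n_reps`` times, refits, and
    reports the median and 2.5/97.5 percentile of every parameter. When a
    ``reference`` fit is given (default: a fit on the original data), the
    column ``within_ci`` flags whether its estimate falls inside the
    bootstrap 95% interval. Replicates that fail to converge are dropped
    and counted in ``df.attrs['n_failed']``.
    """
    structure = structure or ModelStructure.published()
    config = config or FitConfig()
    if n_reps < 50:
        warnings.warn("fewer than 50 bootstrap replicates gives unstable CIs",
                      stacklevel=2)
    subjects = list(dataset)
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = fit_population(subjects, structure, config)
    # start replicates at the reference estimate for speed and stability
    rep_config = replace(
        config,
        theta_cl0=reference.theta_cl,
        theta_v0=reference.theta_v,
        omega2_0=max(reference.omega2_cl, _VAR_FLOOR),
        delta2_prop0=max(reference.delta2_prop, _VAR_FLOOR),
        delta2_add0=max(reference.delta2_add, _VAR_FLOOR),
    )
    rows = []
    n_failed = 0
    for _ in range(n_reps):
        idx = rng.integers(0, len(subjects), size=len(subjects))
        sample = [subjects[i] for i in idx]
        try:
            fit = fit_population(sample, structure, rep_config)
        except Exception:
            n_failed += 1
            continue
        if not np.isfinite(fit.ofv):
            n_failed += 1
            continue
        row = {"theta_cl": fit.theta_cl, "theta_v": fit.theta_v,
               "omega2_cl": fit.omega2_cl, "omega2_v": fit.omega2_v,
               "delta2_prop": fit.delta2_prop, "delta2_add": fit.delta2_add}
        for t, b in fit.betas.items():
            row[f"beta_{t.param}_{t.cov}"] = b
        rows.append(row)
    reps = pd.DataFrame(rows)
    ref_row = {"theta_cl": reference.theta_cl, "theta_v": reference.theta_v,
               "omega2_cl": reference.omega2_cl, "omega2_v": reference.omega2_v,
               "delta2_prop": reference.delta2_prop, "delta2_add": reference.delta2_add}
    for t, b in reference.betas.items():
        ref_row[f"beta_{t.param}_{t.cov}"] = b
    out = pd.DataFrame({
        "estimate": pd.Series(ref_row),
        "median": reps.median(),
        "ci_lo": reps.quantile(0.025),
        "ci_hi": reps.quantile(0.975),
    })
    out["within_ci"] = (out["estimate"] >= out["ci_lo"]) & (out["estimate"] <= out["ci_hi"])
    out.attrs["n_failed"] = n_failed
    out.attrs["n_reps"] = n_reps
    return out
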