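"""The published vancomycin population-PK model for sepsis patients.

Final covariate model (typical values; eta = interindividual random effect):

    CL = 3.35 * (CLCR/93)^0.997 * exp(-0.151 * CCI/5.62) * exp(eta_1)   [L/h]
    V  = 98.5 * (WT/84)^0.205 * exp(eta_2)                              [L]

Interindividual variability is lognormal (eta ~ N(0, omega^2)); four
residual-error models (additive, proportional, combined, exponential)
relate predicted to observed concentrations, the combined model being the
one retained by the published analysis.

Note on units: the source prints typical clearance as "3.35 mL/min".
This package uses L/h throughout — 3.35 L/h is the pharmacologically
consistent reading (a vancomycin CL of 3.35 mL/min ~ 0.2 L/h would be
renal-failure territory and is inconsistent with mg/L * h exposure math).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .pk import PKParameters

__all__ = [
    "FixedEffects",
    "RandomEffects",
    "VarianceComponents",
    "ResidualModelType",
    "Covariates",
    "PopulationModel",
    "typical_params",
    "individual_params",
    "apply_residual",
    "residual_variance",
    "PUBLISHED_MODEL",
]


@dataclass(frozen=True)
class FixedEffects:
    """Typical-value parameters and covariate coefficients of the final model."""

    theta_cl: float = 3.35  # typical CL (L/h) at CLCR=93, CCI=0
    beta_clcr: float = 0.997  # power exponent on CLCR/93
    beta_cci: float = -0.151  # exponential coefficient on CCI/5.62
    theta_v: float = 98.5  # typical V (L) at WT=84
    beta_wt: float = 0.205  # power exponent on WT/84
    ref_clcr: float = 93.0
    ref_cci: float = 5.62
    ref_wt: float = 84.0

    def __post_init__(self) -> None:
        if self.theta_cl <= 0 or self.theta_v <= 0:
            raise ValueError("typical CL and V must be > 0")
        if min(self.ref_clcr, self.ref_cci, self.ref_wt) <= 0:
            raise ValueError("covariate reference values must be > 0")


@dataclass(frozen=True)
class RandomEffects:
    """Subject-level random effects on CL and V (unitless, lognormal scale)."""

    eta_cl: float = 0.0
    eta_v: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.eta_cl) and np.isfinite(self.eta_v)):
            raise ValueError("random effects must be finite")


@dataclass(frozen=True)
class VarianceComponents:
    """IIV variances (omega^2) and residual variances (delta^2).

    Defaults are typical vancomycin PPK magnitudes — 30% CV on CL and V,
    combined residual with 20% proportional CV and 1 mg/L additive SD —
    used for simulation and as fitting initials; all overridable.
    """

    omega2_cl: float = 0.09
    omega2_v: float = 0.09
    delta2_prop: float = 0.04
    delta2_add: float = 1.0

    def __post_init__(self) -> None:
        if min(self.omega2_cl, self.omega2_v, self.delta2_prop, self.delta2_add) < 0:
            raise ValueError("variance components must be >= 0")


class ResidualModelType(str, enum.Enum):
    """The four candidate residual-error models."""

    ADDITIVE = "additive"
    PROPORTIONAL = "proportional"
    COMBINED = "combined"
    EXPONENTIAL = "exponential"


@dataclass(frozen=True)
class Covariates:
    """Per-subject covariates feeding the model and the ML feature tables."""

    clcr: float  # creatinine clearance, mL/min
    cci: float  # Charlson Comorbidity Index score
    wt: float  # body weight, kg
    age: float = 65.0  # years
    sex: int = 1  # 1 = male, 0 = female
    hct: float = 29.6  # hematocrit, %
    hgb: float = 9.5  # hemoglobin, g/dL
    rbc: float = 3.24  # red blood cells, 10^6/uL
    dose24: float = 0.0  # total vancomycin dose per 24 h, mg

    def __post_init__(self) -> None:
        if self.clcr <= 0:
            raise ValueError("CLCR must be > 0")
        if self.wt <= 0:
            raise ValueError("weight must be > 0")
        if self.cci < 0:
            raise ValueError("CCI must be >= 0")


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects + variance components + residual-model choice."""

    fixed: FixedEffects = field(default_factory=FixedEffects)
    variances: VarianceComponents = field(default_factory=VarianceComponents)
    residual: ResidualModelType = ResidualModelType.COMBINED

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "fixed": asdict(self.fixed),
            "variances": asdict(self.variances),
            "residual": self.residual.value,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationModel":
        return cls(
            fixed=FixedEffects(**d["fixed"]),
            variances=VarianceComponents(**d["variances"]),
            residual=ResidualModelType(d["residual"]),
        )

    def save(self, path: str | Path) -> None:
        """Write the model document as YAML (or JSON if the suffix is .json)."""
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PopulationModel":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def typical_params(fixed: FixedEffects, cov: Covariates) -> PKParameters:
    """Typical-value CL and V for a subject's covariates (eta = 0).

    CL = theta_cl * (CLCR/ref)^beta_clcr * exp(beta_cci * CCI/ref_cci)
    V  = theta_v  * (WT/ref)^beta_wt
    """
    cl = (
        fixed.theta_cl
        * (cov.clcr / fixed.ref_clcr) ** fixed.beta_clcr
        * np.exp(fixed.beta_cci * (cov.cci / fixed.ref_cci))
    )
    v = fixed.theta_v * (cov.wt / fixed.ref_wt) ** fixed.beta_wt
    return PKParameters(cl=float(cl), v=float(v))


def individual_params(
    fixed: FixedEffects, cov: Covariates, eta: RandomEffects
) -> PKParameters:
    """Individual CL and V: typical values scaled by exp(eta) (lognormal IIV)."""
    typ = typical_params(fixed, cov)
    return PKParameters(
        cl=typ.cl * float(np.exp(eta.eta_cl)),
        v=typ.v * float(np.exp(eta.eta_v)),
    )


def apply_residual(
    cpred: float,
    model: ResidualModelType,
    eps: float,
    eps1: float = 0.0,
) -> float:
    """Map a predicted concentration to an observed one given error draws.

    additive:      Cobs = Cpred + eps
    proportional:  Cobs = Cpred * (1 + eps)
    combined:      Cobs = Cpred * (1 + eps) + eps1
    exponential:   Cobs = Cpred * exp(eps)
    """
    if cpred < 0:
        raise ValueError("cpred must be >= 0")
    model = ResidualModelType(model)
    if model is ResidualModelType.ADDITIVE:
        return cpred + eps
    if model is ResidualModelType.PROPORTIONAL:
        return cpred * (1.0 + eps)
    if model is ResidualModelType.COMBINED:
        return cpred * (1.0 + eps) + eps1
    if model is ResidualModelType.EXPONENTIAL:
        return cpred * float(np.exp(eps))
    raise ValueError(f"unknown residual model {model!r}")  # pragma: no cover


def residual_variance(
    cpred: float | np.ndarray,
    model: ResidualModelType,
    var: VarianceComponents,
) -> float | np.ndarray:
    """Variance of Cobs given Cpred under a residual model.

    Needed by the MAP / Laplace objectives. The exponential model is
    linearised to first order (variance ~ Cpred^2 * delta2_prop).
    """
    model = ResidualModelType(model)
    c2 = np.square(cpred)
    if model is ResidualModelType.ADDITIVE:
        return var.delta2_add * np.ones_like(c2) if np.ndim(cpred) else var.delta2_add
    if model is ResidualModelType.PROPORTIONAL:
        return c2 * var.delta2_prop
    if model is ResidualModelType.COMBINED:
        return c2 * var.delta2_prop + var.delta2_add
    if model is ResidualModelType.EXPONENTIAL:
        return c2 * var.delta2_prop
    raise ValueError(f"unknown residual model {model!r}")  # pragma: no cover


#: the published final model with the package's default variance components
PUBLISHED_MODEL = PopulationModel()
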