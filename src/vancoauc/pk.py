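"""One-compartment IV-infusion kinetics and AUC24 exposure math.

Closed-form concentration-time solution for zero-order infusion with
first-order elimination, multiple-dose superposition, and the modified
(log-linear) trapezoidal AUC24 computed from a peak/trough pair.

Units are fixed throughout the package: mg for dose amounts, hours for
time, L for volumes, L/h for clearance, mg/L for concentrations and
mg*h/L for AUC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DoseEvent",
    "Regimen",
    "PKParameters",
    "ConcentrationPoint",
    "concentration_at",
    "predict_peak_trough",
    "auc24_modified_trapezoid",
    "auc24_reference",
]

#: below this gap in ln(cmax) - ln(cmin) the log-mean collapses to the
#: arithmetic mean (continuous extension of the log-trapezoid)
_LOG_MEAN_EPS = 1e-12


@dataclass(frozen=True)
class DoseEvent:
    """A single intermittent IV infusion.

    Parameters
    ----------
    amount : float
        Drug mass infused (mg).
    start : float
        Infusion start, hours since first dose.
    duration : float
        Infusion length t_inf (h); the zero-order rate is amount/duration.
    """

    amount: float
    start: float
    duration: float

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount}")
        if self.duration <= 0:
            raise ValueError(f"infusion duration must be > 0, got {self.duration}")
        if self.start < 0:
            raise ValueError(f"dose start must be >= 0, got {self.start}")

    @property
    def rate(self) -> float:
        """Zero-order infusion rate (mg/h)."""
        return self.amount / self.duration


@dataclass(frozen=True)
class Regimen:
    """An ordered intermittent-infusion schedule.

    ``interval`` is the nominal dosing interval tau (h) and ``n_per_24h``
    the number of doses given per 24 h, the ``n`` multiplier of the
    AUC24 trapezoid formula.
    """

    events: tuple[DoseEvent, ...]
    interval: float

    def __post_init__(self) -> None:
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        if self.interval <= 0:
            raise ValueError("dosing interval must be > 0")
        starts = [e.start for e in events]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ValueError("dose events must be sorted by start time")

    @property
    def n_per_24h(self) -> int:
        """Doses administered per 24 hours (>= 1)."""
        return max(1, round(24.0 / self.interval))

    @property
    def dose24(self) -> float:
        """Total drug mass given per 24 h (mg) under the nominal schedule."""
        return self.events[-1].amount * self.n_per_24h if self.events else 0.0

    @classmethod
    def intermittent(
        cls,
        amount: float,
        interval: float,
        duration: float,
        n_doses: int,
        first_start: float = 0.0,
    ) -> "Regimen":
        """Build a uniform q-tau schedule of ``n_doses`` identical infusions."""
        events = tuple(
            DoseEvent(amount=amount, start=first_start + i * interval, duration=duration)
            for i in range(n_doses)
        )
        return cls(events=events, interval=interval)


@dataclass(frozen=True)
class PKParameters:
    """Individual clearance CL (L/h) and volume of distribution V (L)."""

    cl: float
    v: float

    def __post_init__(self) -> None:
        if self.cl <= 0:
            raise ValueError(f"CL must be > 0, got {self.cl}")
        if self.v <= 0:
            raise ValueError(f"V must be > 0, got {self.v}")

    @property
    def k(self) -> float:
        """First-order elimination rate constant (1/h)."""
        return self.cl / self.v


@dataclass(frozen=True)
class ConcentrationPoint:
    """One measured (or simulated) concentration.

    ``kind`` annotates the sampling window ("peak", "trough" or "other")
    and ``interval_index`` the dosing interval the sample falls in; both
    drive the peak/trough train-test split downstream.
    """

    time: float
    value: float
    kind: str = "other"
    interval_index: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("sample time must be >= 0")
        if self.value < 0:
            raise ValueError("concentration must be >= 0")
        if self.kind not in ("peak", "trough", "other"):
            raise ValueError(f"unknown sample kind {self.kind!r}")


def _single_dose_conc(
    t: np.ndarray, rate: float, duration: float, cl: float, k: float
) -> np.ndarray:
    """Concentration from one infusion starting at t=0, vectorised over t.

    During infusion:  C = (R0/CL) * (1 - exp(-k t))
    After infusion:   C = (R0/CL) * (1 - exp(-k t_inf)) * exp(-k (t - t_inf))
    which unifies to C = (R0/CL)*(1 - exp(-k*te))*exp(-k*(t-te)), te = min(t, t_inf).
    """
    t = np.asarray(t, dtype=float)
    te = np.clip(t, 0.0, duration)
    with np.errstate(over="ignore"):
        c = (rate / cl) * (1.0 - np.exp(-k * te)) * np.exp(-k * (t - te))
    return np.where(t > 0.0, c, 0.0)


def concentration_at(params: PKParameters, regimen: Regimen, t) -> float | np.ndarray:
    """Predicted concentration (mg/L) at time(s) ``t`` hours since first dose.

    Superposes the closed-form single-infusion solution over every dose
    event of the regimen (linear kinetics). ``t`` may be a scalar or an
    array; negative times raise.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0 (hours since first dose)")
    if not regimen.events:
        warnings.warn("empty regimen: returning 0 concentration", stacklevel=2)
        out = np.zeros_like(t_arr)
        return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out
    k = params.k
    total = np.zeros_like(t_arr)
    for ev in regimen.events:
        total += _single_dose_conc(t_arr - ev.start, ev.rate, ev.duration, params.cl, k)
    if np.ndim(t) == 0:
        return float(total[0])
    return total


def predict_peak_trough(
    params: PKParameters,
    regimen: Regimen,
    peak_time: float,
    trough_time: float,
) -> tuple[float, float]:
    """Model-predicted (Cmax, Cmin) at the two requested sampling clock times.

    Both times are hours since first dose and must fall within one dosing
    interval of each other, with the trough after the peak (the clinical
    peak is drawn 1-2 h after dosing, the trough 0.5-1 h before the next
    dose).
    """
    if trough_time <= peak_time:
        raise ValueError("trough_time must be after peak_time")
    if trough_time - peak_time > regimen.interval:
        raise ValueError("peak and trough must lie within one dosing interval")
    cmax = concentration_at(params, regimen, peak_time)
    cmin = concentration_at(params, regimen, trough_time)
    return float(cmax), float(cmin)


def auc24_modified_trapezoid(
    cmax: float, cmin: float, t_inf: float, dt: float, n: int
) -> float:
    """AUC24 (mg*h/L) from a peak/trough pair by the modified trapezoid.

    AUC24 = ( t_inf*(Cmax+Cmin)/2 + (Cmax-Cmin)*dt / (ln Cmax - ln Cmin) ) * n

    where ``dt`` is the time between the two samples (h), ``t_inf`` the
    infusion duration (h) and ``n`` the number of doses per 24 h. The
    elimination-phase term is the log-trapezoid (log-mean concentration
    times dt); as Cmax -> Cmin it tends continuously to the common value.
    """
    if cmin <= 0:
        raise ValueError("cmin must be > 0 (log undefined)")
    if cmax < cmin:
        raise ValueError("cmax must be >= cmin")
    if t_inf <= 0 or dt <= 0:
        raise ValueError("t_inf and dt must be > 0")
    if n < 1:
        raise ValueError("n (doses per 24 h) must be >= 1")
    # ln cmax - ln cmin computed as -log1p((cmin-cmax)/cmax): exact
    # cancellation-free form, so the log-mean is stable as cmax -> cmin
    log_gap = -math.log1p((cmin - cmax) / cmax)
    if abs(log_gap) < _LOG_MEAN_EPS:
        log_mean = 0.5 * (cmax + cmin)
    else:
        log_mean = (cmax - cmin) / log_gap
    return (t_inf * (cmax + cmin) / 2.0 + log_mean * dt) * n


def auc24_reference(params: PKParameters, regimen: Regimen) -> float:
    """Exact steady-state AUC24 = 24-h dose / CL (mg*h/L).

    Serves as the closed-form oracle against which the trapezoidal
    approximation is validated; assumes the regimen has reached steady
    state under linear kinetics.
    """
    return regimen.dose24 / params.cl
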