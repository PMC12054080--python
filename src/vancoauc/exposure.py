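"""The four AUC24 prediction strategies and their evaluation.

Given a testing-set subject with a recorded peak/trough pair, each
method produces (Cmax, Cmin) and converts them to AUC24 with the
modified trapezoid:

* ``ppk``      — typical population parameters from covariates alone
                 (no concentrations used);
* ``bayesian`` — MAP-estimated individual parameters from the subject's
                 available concentrations;
* ``ml`` / ``hybrid`` — a trained concentration model queried at the
                 peak and trough feature rows.

The "true" AUC24 a prediction is scored against is the same trapezoid
applied to the measured pair, exactly as exposure is established
clinically from a peak/trough TDM draw. Predictions are summarised with
MAE, MSE, RMSE, MAPE, R^2 and F30 (fraction of predictions within
+/-30% relative error).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import SubjectData, map_estimate
from .ml import HYBRID_FEATURES, ML_FEATURES, predict_concentration
from .pk import auc24_modified_trapezoid, predict_peak_trough
from .popmodel import PopulationModel, typical_params

__all__ = [
    "ExposureEstimate",
    "MetricsReport",
    "METHODS",
    "predict_exposure",
    "true_auc24",
    "evaluate",
    "run_benchmark",
]

METHODS = ("ppk", "bayesian", "ml", "hybrid")


@dataclass(frozen=True)
class ExposureEstimate:
    """Predicted exposure for one subject under one method."""

    method: str
    subject_id: str
    cmax: float
    cmin: float
    auc24: float

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.auc24 <= 0:
            raise ValueError("AUC24 must be > 0")
        if self.cmax < self.cmin:
            raise ValueError("cmax must be >= cmin")


@dataclass(frozen=True)
class MetricsReport:
    """Prediction-error summary for one method over a testing set."""

    mae: float
    mse: float
    rmse: float
    mape: float  # percent
    r2: float
    f30: float  # percent of predictions within +/-30% relative error
    n: int


def _peak_trough_obs(subject: SubjectData):
    """The subject's qualifying measured peak/trough pair (same interval)."""
    peaks = {o.interval_index: o for o in subject.observations if o.kind == "peak"}
    troughs = {o.interval_index: o for o in subject.observations if o.kind == "trough"}
    shared = sorted(set(peaks) & set(troughs))
    if not shared:
        raise ValueError(
            f"subject {subject.id} lacks a peak/trough pair in one dosing "
            "interval (not a testing-set subject)"
        )
    m = shared[0]
    return peaks[m], troughs[m]


def true_auc24(subject: SubjectData) -> float:
    """Reference AUC24 from the measured peak/trough pair (trapezoid)."""
    peak, trough = _peak_trough_obs(subject)
    t_inf = subject.regimen.events[0].duration
    dt = trough.time - peak.time
    # assay noise can invert a flat pair; the trapezoid needs cmax >= cmin
    cmax = max(peak.value, trough.value)
    cmin = max(min(peak.value, trough.value), 0.01)
    return auc24_modified_trapezoid(cmax, cmin, t_inf, dt,
                                    subject.regimen.n_per_24h)


def _feature_row(subject: SubjectData, time: float, mode: str,
                 pop: PopulationModel | None, pk_source: str) -> pd.DataFrame:
    starts = [ev.start for ev in subject.regimen.events if ev.start <= time]
    if not starts:
        raise ValueError("requested time precedes all doses")
    tad = time - max(starts)
    c = subject.covariates
    if mode == "ml":
        row = {"TAD": tad, "DOSE24": c.dose24, "WT": c.wt, "age": c.age,
               "HCT": c.hct, "RBC": c.rbc, "hemoglobin": c.hgb, "CLCR": c.clcr}
        cols = list(ML_FEATURES)
    else:
        if pk_source == "map":
            params = map_estimate(subject, pop).params
        else:
            params = typical_params(pop.fixed, subject.covariates)
        row = {"TAD": tad, "DOSE24": c.dose24, "CL": params.cl, "V": params.v,
               "age": c.age, "WT": c.wt, "HCT": c.hct, "hemoglobin": c.hgb}
        cols = list(HYBRID_FEATURES)
    return pd.DataFrame([row], columns=cols)


def predict_exposure(
    method: str,
    subject: SubjectData,
    pop: PopulationModel | None = None,
    models: dict | None = None,
    pk_source: str = "typical",
) -> ExposureEstimate:
    """Predict a testing-set subject's AUC24 by one of the four methods.

    The subject must carry a measured peak/trough pair: its *times*
    define where every method is evaluated (its *values* are used only
    by the Bayesian method, through MAP estimation, and by the
    reference ``true_auc24``). ``models`` maps 'ml'/'hybrid' to trained
    concentration predictors. ``pk_source`` controls the hybrid
    features at test time: 'typical' keeps the scenario concentration-
    free; 'map' leaks the measured concentrations into CL/V and is for
    sensitivity analysis only.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if method == "bayesian" and not subject.observations:
        raise ValueError(
            "bayesian method needs at least one concentration; "
            "fall back to the ppk method for concentration-free subjects"
        )
    peak, trough = _peak_trough_obs(subject)
    t_inf = subject.regimen.events[0].duration
    dt = trough.time - peak.time
    n = subject.regimen.n_per_24h
    if method == "ppk":
        params = typical_params(pop.fixed, subject.covariates)
        cmax, cmin = predict_peak_trough(params, subject.regimen, peak.time, trough.time)
    elif method == "bayesian":
        if not subject.observations:
            raise ValueError(
                "bayesian method needs at least one concentration; "
                "fall back to the ppk method for concentration-free subjects"
            )
        params = map_estimate(subject, pop).params
        cmax, cmin = predict_peak_trough(params, subject.regimen, peak.time, trough.time)
    else:
        if models is None or method not in models:
            raise ValueError(f"no trained model supplied for method {method!r}")
        model = models[method]
        mode = "ml" if method == "ml" else "hybrid"
        cmax = float(predict_concentration(
            model, _feature_row(subject, peak.time, mode, pop, pk_source))[0])
        cmin = float(predict_concentration(
            model, _feature_row(subject, trough.time, mode, pop, pk_source))[0])
    cmin = max(cmin, 0.01)  # trapezoid needs a positive trough
    cmax = max(cmax, cmin)
    return ExposureEstimate(
        method=method,
        subject_id=subject.id,
        cmax=cmax,
        cmin=cmin,
        auc24=auc24_modified_trapezoid(cmax, cmin, t_inf, dt, n),
    )


def evaluate(predictions: Sequence[tuple[float, float]]) -> MetricsReport:
    """Metric suite over (predicted, true) pairs.

    MAE = mean|e|, MSE = mean e^2, RMSE = sqrt(MSE),
    MAPE = 100 * mean(|e|/y), R^2 = 1 - SSE/SST (SST about the mean of
    the true values), F30 = 100 * fraction with |e|/y <= 0.30.
    """
    arr = np.asarray(predictions, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) == 0:
        raise ValueError("predictions must be a non-empty sequence of (yhat, y)")
    yhat, y = arr[:, 0], arr[:, 1]
    if np.any(y <= 0):
        raise ValueError("true values must be > 0 for MAPE and F30")
    err = yhat - y
    mse = float(np.mean(err**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum(err**2))
    rel = np.abs(err) / y
    return MetricsReport(
        mae=float(np.mean(np.abs(err))),
        mse=mse,
        rmse=float(np.sqrt(mse)),
        mape=float(100.0 * np.mean(rel)),
        r2=1.0 - sse / sst if sst > 0 else float("nan"),
        f30=float(100.0 * np.mean(rel <= 0.30)),
        n=len(y),
    )


def run_benchmark(
    test_subjects: Sequence[SubjectData],
    pop: PopulationModel,
    models: dict,
    methods: Sequence[str] = METHODS,
    pk_source: str = "typical",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every method on a testing set (comparison-table harness).

    Returns ``(table, records)``: the per-method metric table (rows in
    method order, columns Group/MAE/MSE/RMSE/MAPE/R2/F30/n) and the
    per-subject prediction records (one row per subject x method, with
    relative error) backing box/fit plots.
    """
    test_subjects = list(test_subjects)
    if not test_subjects:
        raise ValueError(
            "empty testing set: run split_train_test and pass its test half"
        )
    records = []
    for s in test_subjects:
        y = true_auc24(s)
        for method in methods:
            est = predict_exposure(method, s, pop=pop, models=models,
                                   pk_source=pk_source)
            records.append({
                "subject": s.id, "method": method, "auc24_pred": est.auc24,
                "auc24_true": y, "cmax_pred": est.cmax, "cmin_pred": est.cmin,
                "rel_error": (est.auc24 - y) / y,
            })
    rec = pd.DataFrame(records)
    rows = []
    for method in methods:
        sub = rec[rec["method"] == method]
        m = evaluate(list(zip(sub["auc24_pred"], sub["auc24_true"])))
        rows.append({"Group": method, "MAE": m.mae, "MSE": m.mse, "RMSE": m.rmse,
                     "MAPE": m.mape, "R2": m.r2, "F30": m.f30, "n": m.n})
    return pd.DataFrame(rows), rec
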