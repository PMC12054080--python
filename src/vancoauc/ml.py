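"""Machine-learning concentration predictors and the hybrid PK-ML arm.

Feature tables are built per concentration observation (target = the
observed concentration). Two modes mirror the two published feature
lists:

* ``ml``      — TAD, DOSE24, WT, age, HCT, RBC, hemoglobin, CLCR
* ``hybrid``  — TAD, DOSE24, CL, V, age, WT, HCT, hemoglobin

where the hybrid mode injects individual PK parameters (CL, V) from the
population model — either MAP-Bayesian estimates or covariate-only
typical values (the concentration-free scenario).

Eight learners are benchmarked by grouped k-fold cross-validation,
features screened with a shadow-feature (Boruta-style) procedure, and
the selected forest tuned by grid search. Per-sample additive
attributions are computed natively for tree ensembles (path
decomposition) and linear models; permutation importance is the
fallback backend.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

from .estimation import SubjectData, map_estimate
from .popmodel import PopulationModel, typical_params

__all__ = [
    "ML_FEATURES",
    "HYBRID_FEATURES",
    "FeatureTable",
    "LearnerSpec",
    "default_learners",
    "build_feature_table",
    "benchmark_learners",
    "boruta_select",
    "feature_importance",
    "tune_and_train",
    "predict_concentration",
    "DEFAULT_FOREST_GRID",
]

log = logging.getLogger(__name__)

ML_FEATURES = ("TAD", "DOSE24", "WT", "age", "HCT", "RBC", "hemoglobin", "CLCR")
HYBRID_FEATURES = ("TAD", "DOSE24", "CL", "V", "age", "WT", "HCT", "hemoglobin")

_LEARNER_NAMES = (
    "elastic_net", "knn", "linear", "neural_net",
    "random_forest", "decision_tree", "svm", "xgboost",
)


@dataclass
class FeatureTable:
    """Per-observation design matrix + target, with subject grouping."""

    X: pd.DataFrame
    y: pd.Series  # observed concentration, mg/L
    groups: pd.Series  # subject id per row (grouping unit for CV folds)
    mode: str  # 'ml' or 'hybrid'

    def __post_init__(self) -> None:
        if self.mode not in ("ml", "hybrid"):
            raise ValueError("mode must be 'ml' or 'hybrid'")
        expected = HYBRID_FEATURES if self.mode == "hybrid" else ML_FEATURES
        if tuple(self.X.columns) != expected:
            raise ValueError(
                f"{self.mode} feature table must have columns {expected}, "
                f"got {tuple(self.X.columns)}"
            )
        if self.X.isna().any().any():
            raise ValueError("feature table contains missing values")

    def __len__(self) -> int:
        return len(self.X)

    # CSV + sidecar schema round-trip -----------------------------------
    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        df = self.X.copy()
        df["__target__"] = self.y.values
        df["__subject__"] = self.groups.values
        df.to_csv(path, index=False)
        schema = {"mode": self.mode, "features": list(self.X.columns),
                  "target": "__target__", "group": "__subject__"}
        path.with_suffix(".schema.json").write_text(json.dumps(schema, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        schema = json.loads(path.with_suffix(".schema.json").read_text())
        df = pd.read_csv(path)
        return cls(
            X=df[schema["features"]],
            y=df[schema["target"]].rename("conc"),
            groups=df[schema["group"]].rename("subject"),
            mode=schema["mode"],
        )


@dataclass(frozen=True)
class LearnerSpec:
    """One of the eight benchmarked regression learners."""

    name: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _LEARNER_NAMES:
            raise ValueError(f"unknown learner {self.name!r}; "
                             f"choose from {_LEARNER_NAMES}")

    def build(self, seed: int = 0):
        hp = dict(self.hyperparameters)
        seed = int(seed) % (2**31)
        if self.name == "elastic_net":
            return Pipeline([("scale", StandardScaler()),
                             ("est", ElasticNet(random_state=seed, **hp))])
        if self.name == "knn":
            return Pipeline([("scale", StandardScaler()),
                             ("est", KNeighborsRegressor(**hp))])
        if self.name == "linear":
            return LinearRegression(**hp)
        if self.name == "neural_net":
            hp.setdefault("hidden_layer_sizes", (32,))
            hp.setdefault("max_iter", 500)
            return Pipeline([("scale", StandardScaler()),
                             ("est", MLPRegressor(random_state=seed, **hp))])
        if self.name == "random_forest":
            hp.setdefault("n_estimators", 500)
            hp.setdefault("max_features", 1 / 3)
            return RandomForestRegressor(random_state=seed, n_jobs=1, **hp)
        if self.name == "decision_tree":
            return DecisionTreeRegressor(random_state=seed, **hp)
        if self.name == "svm":
            return Pipeline([("scale", StandardScaler()), ("est", SVR(**hp))])
        if self.name == "xgboost":
            hp.setdefault("n_estimators", 300)
            hp.setdefault("verbosity", 0)
            return XGBRegressor(random_state=seed, n_jobs=1, **hp)
        raise AssertionError(self.name)


def default_learners() -> list[LearnerSpec]:
    """The eight-algorithm benchmarking panel with default settings."""
    return [LearnerSpec(name) for name in _LEARNER_NAMES]


# ----------------------------------------------------------------------
# feature construction
# ----------------------------------------------------------------------

def build_feature_table(
    subjects: Sequence[SubjectData],
    mode: str = "ml",
    pop: PopulationModel | None = None,
    pk_source: str = "typical",
) -> FeatureTable:
    """One feature row per concentration observation.

    TAD is the time since the most recent dose start; observations with
    no preceding dose are excluded (logged), mirroring the cohort rule
    that drops samples without prior dosing information. Hybrid mode
    attaches individual CL and V from ``pop`` via MAP estimation
    (``pk_source='map'``) or typical covariate-only values
    (``pk_source='typical'``, the concentration-free default).
    """
    if mode not in ("ml", "hybrid"):
        raise ValueError("mode must be 'ml' or 'hybrid'")
    if mode == "hybrid":
        if pop is None:
            raise ValueError("hybrid mode requires a population model")
        if pk_source not in ("map", "typical"):
            raise ValueError("pk_source must be 'map' or 'typical'")
    rows, targets, groups = [], [], []
    n_dropped = 0
    for s in subjects:
        if mode == "hybrid":
            if pk_source == "map":
                params = map_estimate(s, pop).params
            else:
                params = typical_params(pop.fixed, s.covariates)
        starts = [ev.start for ev in s.regimen.events]
        for o in s.observations:
            prior = [t for t in starts if t <= o.time]
            if not prior:
                n_dropped += 1
                continue
            tad = o.time - max(prior)
            c = s.covariates
            if mode == "ml":
                row = {"TAD": tad, "DOSE24": c.dose24, "WT": c.wt, "age": c.age,
                       "HCT": c.hct, "RBC": c.rbc, "hemoglobin": c.hgb,
                       "CLCR": c.clcr}
            else:
                row = {"TAD": tad, "DOSE24": c.dose24, "CL": params.cl,
                       "V": params.v, "age": c.age, "WT": c.wt, "HCT": c.hct,
                       "hemoglobin": c.hgb}
            rows.append(row)
            targets.append(o.value)
            groups.append(s.id)
    if n_dropped:
        log.info("build_feature_table: dropped %d observation(s) with no "
                 "preceding dose", n_dropped)
    cols = list(HYBRID_FEATURES if mode == "hybrid" else ML_FEATURES)
    X = pd.DataFrame(rows, columns=cols)
    return FeatureTable(X=X, y=pd.Series(targets, name="conc"),
                        groups=pd.Series(groups, name="subject"), mode=mode)


# ----------------------------------------------------------------------
# cross-validated benchmarking
# ----------------------------------------------------------------------

def _grouped_folds(groups: pd.Series, folds: int, seed: int) -> list[np.ndarray]:
    """Seeded k-fold partition of subjects (not rows), so no subject's
    observations leak across folds."""
    ids = groups.unique()
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    assignment = {ids[j]: perm[j] % folds for j in range(len(ids))}
    fold_of_row = groups.map(assignment).to_numpy()
    return [np.flatnonzero(fold_of_row == f) for f in range(folds)]


def benchmark_learners(
    table: FeatureTable,
    specs: Sequence[LearnerSpec] | None = None,
    folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Grouped k-fold CV of each learner; report sorted by MAE.

    Returns a DataFrame indexed by learner name with columns MAE, MSE,
    RMSE, R2 (pooled out-of-fold predictions). Learners that fail on any
    fold are flagged (``failed=True``) with NaN metrics.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(table) == 0:
        raise ValueError("empty feature table")
    specs = list(specs) if specs is not None else default_learners()
    fold_idx = _grouped_folds(table.groups, folds, seed)
    X, y = table.X.to_numpy(dtype=float), table.y.to_numpy(dtype=float)
    rows = {}
    for spec in specs:
        pred = np.full(len(y), np.nan)
        failed = False
        for f, test_idx in enumerate(fold_idx):
            if len(test_idx) == 0:
                continue
            train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est = spec.build(seed=seed)
                    est.fit(X[train_idx], y[train_idx])
                    pred[test_idx] = est.predict(X[test_idx])
            except Exception:  # noqa: BLE001 - a failing learner is reported, not fatal
                log.warning("learner %s failed on fold %d", spec.name, f)
                failed = True
        ok = ~np.isnan(pred)
        if failed or not ok.any():
            rows[spec.name] = {"MAE": np.nan, "MSE": np.nan, "RMSE": np.nan,
                               "R2": np.nan, "failed": True}
            continue
        err = pred[ok] - y[ok]
        mse = float(np.mean(err**2))
        sst = float(np.sum((y[ok] - y[ok].mean()) ** 2))
        rows[spec.name] = {
            "MAE": float(np.mean(np.abs(err))),
            "MSE": mse,
            "RMSE": float(np.sqrt(mse)),
            "R2": 1.0 - float(np.sum(err**2)) / sst if sst > 0 else np.nan,
            "failed": False,
        }
    report = pd.DataFrame.from_dict(rows, orient="index")
    report = report.astype({"MAE": float, "MSE": float, "RMSE": float,
                            "R2": float, "failed": bool})
    report = report.sort_values("MAE")
    report.attrs["folds"] = folds
    report.attrs["seed"] = seed
    return report


# ----------------------------------------------------------------------
# shadow-feature (Boruta-style) selection
# ----------------------------------------------------------------------

def boruta_select(
    table: FeatureTable,
    n_iter: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
    forest_kwargs: dict | None = None,
) -> dict[str, str]:
    """All-relevant feature screening against permuted shadow copies.

    Each iteration appends a permuted copy of every feature, fits a
    random forest, and counts a "hit" for every real feature whose
    importance beats the best shadow importance. A two-sided binomial
    test at ``alpha`` (Bonferroni-corrected across features) classifies
    each feature as confirmed (> chance), rejected (< chance) or
    tentative.
    """
    if n_iter < 20:
        raise ValueError("n_iter must be >= 20 for a meaningful binomial test")
    X = table.X.to_numpy(dtype=float)
    y = table.y.to_numpy(dtype=float)
    n, p = X.shape
    if n < p:
        raise ValueError("fewer rows than features")
    rng = np.random.default_rng(seed)
    kw = {"n_estimators": 100, "max_features": 1 / 3, "n_jobs": 1}
    kw.update(forest_kwargs or {})
    hits = np.zeros(p, dtype=int)
    for it in range(n_iter):
        shadow = X.copy()
        for j in range(p):
            shadow[:, j] = rng.permutation(shadow[:, j])
        Xa = np.hstack([X, shadow])
        rf = RandomForestRegressor(random_state=int(rng.integers(2**31)), **kw)
        rf.fit(Xa, y)
        imp = rf.feature_importances_
        best_shadow = imp[p:].max()
        hits += imp[:p] > best_shadow
    out = {}
    thr = alpha / p  # Bonferroni across features
    for j, name in enumerate(table.X.columns):
        more = stats.binomtest(int(hits[j]), n_iter, 0.5, alternative="greater")
        less = stats.binomtest(int(hits[j]), n_iter, 0.5, alternative="less")
        if more.pvalue < thr:
            out[name] = "confirmed"
        elif less.pvalue < thr:
            out[name] = "rejected"
        else:
            out[name] = "tentative"
    return out


# ----------------------------------------------------------------------
# per-sample attributions
# ----------------------------------------------------------------------

def _tree_path_attributions(tree, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact additive attribution for one fitted sklearn tree.

    Walking each sample's root-to-leaf path, the change in node value at
    every split is credited to the split feature; attributions therefore
    sum to prediction minus the root (baseline) value exactly.
    """
    t = tree.tree_
    values = t.value[:, 0, 0]
    contrib = np.zeros_like(X, dtype=float)
    node_indicator = t.decision_path(X.astype(np.float32))
    indptr, indices = node_indicator.indptr, node_indicator.indices
    for i in range(X.shape[0]):
        path = indices[indptr[i]:indptr[i + 1]]
        for parent, child in zip(path[:-1], path[1:]):
            contrib[i, t.feature[parent]] += values[child] - values[parent]
    return contrib, float(values[0])


def feature_importance(model, table: FeatureTable, seed: int = 0) -> pd.DataFrame:
    """Per-sample signed feature contributions (swarm-plot data).

    Backends, in order of preference:

    * tree ensembles / single trees — exact path-decomposition
      attributions (additive: rows sum to prediction - baseline);
    * linear models — coef * (x - mean) (additive);
    * anything else — permutation importance, broadcast per sample as
      importance * sign(correlation with prediction) (not additive).

    Returns a DataFrame (rows = samples, columns = features) with
    ``attrs['baseline']`` and ``attrs['additive']``.
    """
    X = table.X.to_numpy(dtype=float)
    cols = list(table.X.columns)
    est = model.named_steps["est"] if isinstance(model, Pipeline) else model
    if isinstance(est, RandomForestRegressor):
        if not hasattr(est, "estimators_"):
            raise ValueError("model is not fitted")
        contrib = np.zeros_like(X, dtype=float)
        base = 0.0
        for t in est.estimators_:
            c, b = _tree_path_attributions(t, X)
            contrib += c
            base += b
        contrib /= len(est.estimators_)
        base /= len(est.estimators_)
        additive = True
    elif isinstance(est, DecisionTreeRegressor):
        if not hasattr(est, "tree_"):
            raise ValueError("model is not fitted")
        contrib, base = _tree_path_attributions(est, X)
        additive = True
    elif hasattr(est, "coef_") and not isinstance(model, Pipeline):
        if est.coef_ is None:
            raise ValueError("model is not fitted")
        mean = X.mean(axis=0)
        contrib = (X - mean) * np.asarray(est.coef_).ravel()
        base = float(model.predict(mean[None, :])[0])
        additive = True
    else:
        from sklearn.inspection import permutation_importance

        if not hasattr(est, "predict"):
            raise ValueError("model is not fitted")
        pi = permutation_importance(
            model, X, table.y.to_numpy(dtype=float), n_repeats=10,
            random_state=int(seed) % (2**31), scoring="neg_mean_absolute_error",
        )
        pred = model.predict(X)
        signs = np.array([
            np.sign(np.corrcoef(X[:, j], pred)[0, 1]) if X[:, j].std() > 0 else 0.0
            for j in range(X.shape[1])
        ])
        contrib = np.tile(pi.importances_mean * signs, (X.shape[0], 1))
        base = float(np.mean(pred))
        additive = False
    out = pd.DataFrame(contrib, columns=cols)
    out.attrs["baseline"] = base
    out.attrs["additive"] = additive
    return out


# ----------------------------------------------------------------------
# tuning and prediction
# ----------------------------------------------------------------------

DEFAULT_FOREST_GRID: tuple[dict, ...] = tuple(
    {"n_estimators": n, "max_depth": d, "min_samples_leaf": m}
    for n in (100, 500, 1000)
    for d in (4, 8, None)
    for m in (1, 5, 10)
)


def tune_and_train(
    table: FeatureTable,
    grid: Sequence[dict] | None = None,
    folds: int = 10,
    seed: int = 0,
    learner: str = "random_forest",
) -> tuple[object, dict]:
    """Grid search by grouped-CV MAE, then refit the winner on all rows.

    The learner's default configuration is always part of the grid, so
    the tuned CV R^2 can never fall below the untuned one. Returns
    (fitted model, report) where the report holds the chosen
    hyperparameters and before/after CV metrics.
    """
    grid = list(grid) if grid is not None else list(DEFAULT_FOREST_GRID)
    default_hp: dict = {}
    if not any(g == default_hp for g in grid):
        grid = [default_hp] + grid
    results = []
    for hp in grid:
        spec = LearnerSpec(learner, hyperparameters=hp)
        rep = benchmark_learners(table, [spec], folds=folds, seed=seed)
        row = rep.iloc[0]
        if row.get("failed", False):
            raise ValueError(f"grid entry {hp!r} is invalid for {learner}")
        results.append((float(row["MAE"]), float(row["R2"]), hp))
    results_sorted = sorted(results, key=lambda r: (r[0], grid.index(r[2])))
    best_mae, best_r2, best_hp = results_sorted[0]
    default_row = next(r for r in results if r[2] == default_hp)
    model = LearnerSpec(learner, hyperparameters=best_hp).build(seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(table.X.to_numpy(dtype=float), table.y.to_numpy(dtype=float))
    report = {
        "learner": learner,
        "best_hyperparameters": best_hp,
        "cv_mae": best_mae,
        "cv_r2": best_r2,
        "default_cv_mae": default_row[0],
        "default_cv_r2": default_row[1],
        "folds": folds,
        "seed": seed,
        "features": list(table.X.columns),
        "mode": table.mode,
    }
    return model, report


def predict_concentration(model, features: pd.DataFrame | pd.Series) -> np.ndarray:
    """Predict concentration(s), clipping negative raw outputs to zero."""
    if isinstance(features, pd.Series):
        features = features.to_frame().T
    raw = np.asarray(model.predict(features.to_numpy(dtype=float)), dtype=float)
    if (raw < 0).any():
        log.info("predict_concentration: clipped %d negative prediction(s)",
                 int((raw < 0).sum()))
    return np.clip(raw, 0.0, None)


def save_model_bundle(model, report: dict, path: str | Path) -> None:
    """Persist a trained model + metadata (pickle + JSON sidecar)."""
    import pickle

    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump(model, fh)
    path.with_suffix(".meta.json").write_text(json.dumps(report, indent=2, default=str))


def load_model_bundle(path: str | Path) -> tuple[object, dict]:
    import pickle

    path = Path(path)
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    return model, meta
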