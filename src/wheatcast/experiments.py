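"""Study orchestration on synthetic scenes.

Reproduces the analysis protocols around the yield models:

* feature-combination comparison over the six canonical input sets
  {TS, Climate, SIF, TS+Climate, TS+SIF, TS+Climate+SIF}, where
  TS = {EVI, LAI} and Climate = the six reanalysis-style variables;
* tree-ensemble baselines (Random Forest, XGBoost) on flattened
  sequences with 5-fold cross-validation;
* stepwise early-season estimation (progressively longer input windows,
  fixed hyperparameters, fixed test split);
* drought-year validation by leave-one-year-out, quantifying what SIF
  adds on the held-out drought season;
* cross-region application of a frozen model, reported as an
  official/estimated/accuracy table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from xgboost import XGBRegressor

from . import bayesopt
from .containers import SampleSet
from .model import BCBLConfig, CNNBiLSTMYield, LSTMYield, YieldFitResults
from .preprocess import NormalizationParams, normalize_minmax
from .evaluation import (
    MetricsReport,
    accuracy_ratio,
    compute_metrics,
    kfold,
    leave_one_year_out,
    split_train_test,
)

logger = logging.getLogger(__name__)

#: The six canonical feature combinations.
FEATURE_COMBOS: dict[str, tuple[str, ...]] = {
    "TS": ("EVI", "LAI"),
    "Climate": ("T2m", "Tmn", "Tmx", "Pre", "U10m", "V10m"),
    "SIF": ("SIF",),
    "TS+Climate": ("EVI", "LAI", "T2m", "Tmn", "Tmx", "Pre", "U10m", "V10m"),
    "TS+SIF": ("EVI", "LAI", "SIF"),
    "TS+Climate+SIF": ("EVI", "LAI", "SIF", "T2m", "Tmn", "Tmx", "Pre", "U10m", "V10m"),
}

DEEP_MODELS = {"BCBL": CNNBiLSTMYield, "LSTM": LSTMYield}
TREE_MODELS = ("RF", "XGBoost")


@dataclass
class ExperimentConfig:
    """Settings shared by the experiment drivers."""

    feature_combos: tuple[str, ...] = tuple(FEATURE_COMBOS)
    models: tuple[str, ...] = ("BCBL", "LSTM", "RF", "XGBoost")
    model_config: BCBLConfig = field(default_factory=BCBLConfig)
    train_fraction: float = 0.8
    cv_folds: int = 5
    tune: bool = False
    bo_init_points: int = 10
    bo_n_iter: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.feature_combos:
            raise ValueError("need at least one feature combination")
        unknown = [c for c in self.feature_combos if c not in FEATURE_COMBOS]
        if unknown:
            raise ValueError(f"unknown feature combos: {unknown}")


# ---------------------------------------------------------------------------
# deep-model protocol (random 80/20 split)


def train_eval_deep(
    samples: SampleSet,
    model_name: str,
    config: BCBLConfig,
    seed: int,
    train_fraction: float = 0.8,
) -> tuple[MetricsReport, YieldFitResults, NormalizationParams]:
    """80/20 protocol for a deep model on an already feature-selected set.

    Normalization statistics are learned on the training split only and
    frozen for the test transform.
    """
    cls = DEEP_MODELS[model_name]
    idx = np.arange(len(samples))
    train_idx, test_idx = split_train_test(idx, train_fraction, seed)
    train, test = samples.take(train_idx), samples.take(test_idx)

    Xtr, norm = normalize_minmax(train.X, feature_names=samples.feature_names)
    Xte, _ = normalize_minmax(test.X, params=norm)

    model = cls(train.y, Xtr, replace(config, seed=seed))
    model.norm_params = norm
    res = model.fit()
    pred = res.predict(Xte)
    report = compute_metrics(test.y, pred)
    return report, res, norm


# ---------------------------------------------------------------------------
# tree baselines (5-fold CV on flattened sequences)


def flatten_sequences(X: np.ndarray) -> np.ndarray:
    """(N, T, F) -> (N, T*F); row-major, so time is the fast axis per feature block."""
    return np.asarray(X, float).reshape(X.shape[0], -1)


def _make_tree(model_kind: str, params: dict, seed: int):
    if model_kind == "RF":
        return RandomForestRegressor(
            n_estimators=int(params.get("n_estimators", 200)),
            max_depth=int(params["max_depth"]) if params.get("max_depth") else None,
            random_state=seed,
            n_jobs=1,
        )
    if model_kind == "XGBoost":
        return XGBRegressor(
            n_estimators=int(params.get("n_estimators", 200)),
            max_depth=int(params.get("max_depth", 6)),
            learning_rate=float(params.get("learning_rate", 0.1)),
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    raise ValueError(f"unknown tree model {model_kind!r}")


def tree_cv_metrics(
    samples: SampleSet, model_kind: str, params: dict, seed: int, k: int = 5
) -> tuple[MetricsReport, list[MetricsReport]]:
    """k-fold CV of a tree ensemble; metrics averaged over folds."""
    if np.ptp(samples.y) == 0:
        raise ValueError("degenerate targets: zero range")
    Xf = flatten_sequences(samples.X)
    folds = kfold(np.arange(len(samples)), k=k, seed=seed)
    fold_reports = []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(samples)), test_idx)
        est = _make_tree(model_kind, params, seed)
        est.fit(Xf[train_idx], samples.y[train_idx])
        pred = est.predict(Xf[test_idx])
        fold_reports.append(compute_metrics(samples.y[test_idx], pred))
    mean = MetricsReport(
        r2=float(np.mean([r.r2 for r in fold_reports])),
        rmse=float(np.mean([r.rmse for r in fold_reports])),
        mre=float(np.mean([r.mre for r in fold_reports])),
        n=int(sum(r.n for r in fold_reports)),
    )
    return mean, fold_reports


TREE_SPACES = {
    "RF": bayesopt.SearchSpace(
        [
            bayesopt.Parameter("n_estimators", 50, 300, kind="integer"),
            bayesopt.Parameter("max_depth", 3, 15, kind="integer"),
        ]
    ),
    "XGBoost": bayesopt.SearchSpace(
        [
            bayesopt.Parameter("n_estimators", 50, 300, kind="integer"),
            bayesopt.Parameter("max_depth", 2, 10, kind="integer"),
            bayesopt.Parameter("learning_rate", 0.01, 0.3, scale="log"),
        ]
    ),
}


def run_baseline_trees(
    samples: SampleSet,
    model_kind: str,
    seed: int = 0,
    tune: bool = False,
    bo_init_points: int = 10,
    bo_n_iter: int = 50,
    k: int = 5,
) -> tuple[MetricsReport, dict]:
    """Tree-ensemble baseline; optional Bayesian tuning of its hyperparameters.

    The tuning objective is the mean cross-validated RMSE.
    """
    params: dict = {}
    if tune:
        def objective(p: dict) -> float:
            report, _ = tree_cv_metrics(samples, model_kind, p, seed, k=k)
            return report.rmse

        best, _ = bayesopt.optimize(
            objective, TREE_SPACES[model_kind], init_points=bo_init_points,
            n_iter=bo_n_iter, seed=seed,
        )
        params = best.params
    report, _ = tree_cv_metrics(samples, model_kind, params, seed, k=k)
    return report, params


# ---------------------------------------------------------------------------
# deep-model hyperparameter tuning


def tune_deep_model(
    samples: SampleSet,
    model_name: str = "BCBL",
    base_config: BCBLConfig | None = None,
    space: bayesopt.SearchSpace | None = None,
    init_points: int = 10,
    n_iter: int = 50,
    seed: int = 0,
) -> tuple[BCBLConfig, list[bayesopt.TrialRecord]]:
    """Bayesian-optimize the model hyperparameters.

    The objective is the RMSE (kg/ha) on an inner 20% validation split of
    the training data.
    """
    base = base_config or BCBLConfig()
    space = space or bayesopt.default_bcbl_space()
    idx = np.arange(len(samples))
    train_idx, val_idx = split_train_test(idx, 0.8, seed)
    train, val = samples.take(train_idx), samples.take(val_idx)
    Xtr, norm = normalize_minmax(train.X, feature_names=samples.feature_names)
    Xva, _ = normalize_minmax(val.X, params=norm)

    def objective(p: dict) -> float:
        cfg = replace(base, seed=seed, **{k: v for k, v in p.items() if hasattr(base, k)})
        model = DEEP_MODELS[model_name](train.y, Xtr, cfg)
        res = model.fit()
        pred = res.predict(Xva)
        return float(np.sqrt(np.mean((pred - val.y) ** 2)))

    best, history = bayesopt.optimize(objective, space, init_points, n_iter, seed)
    tuned = replace(base, **{k: v for k, v in best.params.items() if hasattr(base, k)})
    return tuned, history


# ---------------------------------------------------------------------------
# experiment drivers


def feature_combination_run(samples: SampleSet, config: ExperimentConfig) -> pd.DataFrame:
    """Metrics per (feature combination, model).

    Deep models follow the 80/20 protocol; tree baselines report the mean
    over 5 cross-validation folds.
    """
    missing = {
        f for c in config.feature_combos for f in FEATURE_COMBOS[c]
    } - set(samples.feature_names)
    if missing:
        raise KeyError(f"scene lacks features: {sorted(missing)}")

    rows = []
    for combo in config.feature_combos:
        sub = samples.select_features(FEATURE_COMBOS[combo])
        for model_name in config.models:
            if model_name in DEEP_MODELS:
                cfg = config.model_config
                if config.tune:
                    cfg, _ = tune_deep_model(
                        sub, model_name, cfg,
                        init_points=config.bo_init_points, n_iter=config.bo_n_iter,
                        seed=config.seed,
                    )
                report, _, _ = train_eval_deep(
                    sub, model_name, cfg, config.seed, config.train_fraction
                )
            else:
                report, _ = run_baseline_trees(
                    sub, model_name, seed=config.seed, tune=config.tune,
                    bo_init_points=config.bo_init_points, bo_n_iter=config.bo_n_iter,
                    k=config.cv_folds,
                )
            logger.info("%s / %s: R2=%.3f RMSE=%.1f", combo, model_name, report.r2, report.rmse)
            rows.append(
                {"combo": combo, "model": model_name, **report.to_dict()}
            )
    return pd.DataFrame(rows)


@dataclass
class StepwiseResult:
    """R2/RMSE trajectory over progressively longer input windows."""

    table: pd.DataFrame  # columns: composites_used, last_day, r2, rmse

    def __post_init__(self) -> None:
        t = self.table["composites_used"].to_numpy()
        if not np.all(np.diff(t) > 0):
            raise ValueError("truncation points must be strictly increasing")


def stepwise_sensitivity(
    samples: SampleSet,
    config: BCBLConfig,
    model_name: str = "BCBL",
    t_min: int = 4,
    stride: int = 1,
    seed: int = 0,
    train_fraction: float = 0.8,
) -> StepwiseResult:
    """Early-season estimation: retrain on composites [0, t) for growing t.

    The train/test split is fixed across truncations; hyperparameters are
    reused unchanged (fresh weights per truncation).  The final point
    always uses the full season.
    """
    T = samples.n_composites
    if T < 3:
        raise ValueError("need at least 3 composites")
    points = list(range(t_min, T + 1, stride))
    if points[-1] != T:
        points.append(T)

    idx = np.arange(len(samples))
    train_idx, test_idx = split_train_test(idx, train_fraction, seed)

    rows = []
    for t in points:
        sub = samples.truncate(t)
        train, test = sub.take(train_idx), sub.take(test_idx)
        Xtr, norm = normalize_minmax(train.X, feature_names=sub.feature_names)
        Xte, _ = normalize_minmax(test.X, params=norm)
        model = DEEP_MODELS[model_name](train.y, Xtr, replace(config, seed=seed))
        res = model.fit()
        report = compute_metrics(test.y, res.predict(Xte))
        last_day = int(sub.composite_dates[-1]) if len(sub.composite_dates) else t * 8
        rows.append(
            {"composites_used": t, "last_day": last_day, "r2": report.r2, "rmse": report.rmse}
        )
        logger.info("stepwise t=%d: R2=%.3f RMSE=%.1f", t, report.r2, report.rmse)
    return StepwiseResult(pd.DataFrame(rows))


def drought_validation(
    samples: SampleSet,
    drought_year: int,
    config: BCBLConfig,
    combos: tuple[str, ...] = ("TS+Climate", "TS+Climate+SIF"),
    model_name: str = "BCBL",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Leave the drought year out, train on the rest, test on the drought year.

    Returns one metrics row per combo plus the SIF deltas (R2 and RMSE
    differences between TS+Climate+SIF and TS+Climate).
    """
    if drought_year not in samples.years:
        raise ValueError(f"drought year {drought_year} not present in the samples")
    if not {"TS+Climate", "TS+Climate+SIF"} <= set(combos):
        raise ValueError("combos must include TS+Climate and TS+Climate+SIF")

    rows = []
    for combo in combos:
        sub = samples.select_features(FEATURE_COMBOS[combo])
        train, test = leave_one_year_out(sub, drought_year)
        Xtr, norm = normalize_minmax(train.X, feature_names=sub.feature_names)
        Xte, _ = normalize_minmax(test.X, params=norm)
        model = DEEP_MODELS[model_name](train.y, Xtr, replace(config, seed=seed))
        res = model.fit()
        report = compute_metrics(test.y, res.predict(Xte))
        rows.append({"combo": combo, **report.to_dict()})
    table = pd.DataFrame(rows).set_index("combo")
    deltas = {
        "delta_r2": float(table.loc["TS+Climate+SIF", "r2"] - table.loc["TS+Climate", "r2"]),
        "delta_rmse": float(
            table.loc["TS+Climate+SIF", "rmse"] - table.loc["TS+Climate", "rmse"]
        ),
    }
    return table.reset_index(), deltas


def cross_region_eval(
    results: YieldFitResults,
    heldout: SampleSet,
    norm_params: NormalizationParams,
) -> tuple[pd.DataFrame, dict]:
    """Apply a frozen model to held-out counties and tabulate accuracy.

    Emits one row per held-out county-year with official yield (oy),
    estimated yield (ey) and accuracy ratio (EY/OY x 100), plus summary
    statistics: mean accuracy and the maximum |100 - AC|.
    """
    if tuple(heldout.feature_names) != tuple(norm_params.feature_names):
        raise ValueError("held-out samples do not match the model's feature schema")
    Xn, _ = normalize_minmax(heldout.X, params=norm_params)
    pred = results.predict(Xn)
    ac = accuracy_ratio(heldout.y, pred)
    table = pd.DataFrame(
        {
            "county_id": heldout.county_ids,
            "year": heldout.years,
            "oy": heldout.y,
            "ey": pred,
            "accuracy": ac,
        }
    )
    summary = {
        "mean_accuracy": float(np.mean(ac)),
        "max_annual_error": float(np.max(np.abs(100.0 - ac))),
    }
    return table, summary
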