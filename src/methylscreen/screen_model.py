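"""Two-layer stacked screening classifier.

Layer 1 holds two gradient-boosting models: HN (cancer vs normal, features
chosen by recursive feature elimination with cross-validation) and HL (cancer
vs benign liver disease, features = importance > 0 after an initial fit).
Their outputs are combined by an L2-penalised logistic regression; the
combiner's decision value h = w.x + b is the t-score.  The stacker is fitted
strictly on out-of-fold layer-1 outputs, and the held-out test split is never
touched until final evaluation -- :func:`audit_no_leakage` verifies both.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.feature_selection import RFECV
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from . import __version__ as _pkg_version
from .cohort_sim import Cohort, feature_frame, label_series
from .metrics_report import ConfusionCounts, confusion_metrics, roc_auc

logger = logging.getLogger(__name__)

HCC = "HCC"


@dataclass
class TrainConfig:
    """Cross-validation and hyperparameter-search settings.

    The boosting grid and RFECV settings are implementer defaults; use
    :meth:`fast` for a reduced grid in quick runs.
    """

    folds: int = 5
    param_grid: dict[str, list] = field(
        default_factory=lambda: {
            "n_estimators": [100, 200],
            "max_depth": [2, 3],
            "learning_rate": [0.1],
        }
    )
    seed: int = 0
    scoring: str = "roc_auc"
    rfecv_step: float = 0.3
    rfecv_min_features: int = 10
    rfecv_folds: int = 3
    lambda_grid: tuple = (0.01, 0.1, 1.0, 10.0, 100.0)

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    @classmethod
    def fast(cls, **overrides) -> "TrainConfig":
        cfg = cls(
            folds=3,
            param_grid={"n_estimators": [50], "max_depth": [2], "learning_rate": [0.1]},
            rfecv_step=0.5,
            rfecv_folds=2,
        )
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg


@dataclass
class LayerOneModel:
    kind: str  # "HN" or "HL"
    estimator: GradientBoostingClassifier
    features: list[str]
    best_params: dict

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of the positive (HCC) class."""
        return self.estimator.predict_proba(X[self.features])[:, 1]


@dataclass
class StackModel:
    hn: LayerOneModel
    hl: LayerOneModel
    logistic: LogisticRegression
    w: np.ndarray
    b: float
    lam: float
    threshold: float = 0.0
    fitted_on_oof: bool = False

    def layer1_outputs(self, X: pd.DataFrame) -> np.ndarray:
        return np.column_stack([self.hn.predict(X), self.hl.predict(X)])

    def t_score(self, X: pd.DataFrame) -> np.ndarray:
        """h = w . (HN(x), HL(x)) + b for each sample."""
        return t_score(self, X)

    def predict_class(self, X: pd.DataFrame, threshold: float | None = None) -> np.ndarray:
        return predict_class(self, self.t_score(X), threshold)


def _check_two_classes(y: np.ndarray, context: str) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError(f"{context}: both classes must be present")


def _grid_search(
    X: pd.DataFrame, y: np.ndarray, config: TrainConfig
) -> GradientBoostingClassifier:
    cv = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    search = GridSearchCV(
        GradientBoostingClassifier(random_state=config.seed),
        config.param_grid,
        scoring=config.scoring,
        cv=cv,
        n_jobs=1,
    )
    search.fit(X, y)
    return search.best_estimator_


def train_hn(X: pd.DataFrame, y: Sequence[int], config: TrainConfig | None = None) -> LayerOneModel:
    """HCC-vs-normal layer-1 model.

    Hyperparameters are grid-searched first; features are then pruned by
    RFECV with cross-validated AUC scoring and the model refitted on the
    surviving features.  Deterministic under ``config.seed``.
    """
    config = config or TrainConfig()
    y = np.asarray(y)
    _check_two_classes(y, "train_hn")
    best = _grid_search(X, y, config)
    selector = RFECV(
        clone(best),
        step=config.rfecv_step,
        min_features_to_select=config.rfecv_min_features,
        cv=StratifiedKFold(config.rfecv_folds, shuffle=True, random_state=config.seed),
        scoring=config.scoring,
        n_jobs=1,
    )
    selector.fit(X, y)
    features = list(X.columns[selector.support_])
    est = clone(best).fit(X[features], y)
    return LayerOneModel(kind="HN", estimator=est, features=features,
                         best_params=best.get_params())


def train_hl(X: pd.DataFrame, y: Sequence[int], config: TrainConfig | None = None) -> LayerOneModel:
    """HCC-vs-liver-disease layer-1 model; keeps every feature with nonzero
    importance after an initial grid-searched fit."""
    config = config or TrainConfig()
    y = np.asarray(y)
    _check_two_classes(y, "train_hl")
    best = _grid_search(X, y, config)
    full = clone(best).fit(X, y)
    mask = full.feature_importances_ > 0
    features = list(X.columns[mask])
    if not features:  # degenerate all-zero importances: keep everything
        features = list(X.columns)
    est = clone(best).fit(X[features], y)
    return LayerOneModel(kind="HL", estimator=est, features=features,
                         best_params=best.get_params())


def train_stack(
    oof_outputs: np.ndarray,
    y: Sequence[int],
    lambda_grid: Sequence[float] | None = None,
    config: TrainConfig | None = None,
    *,
    is_out_of_fold: bool = True,
    allow_in_fold: bool = False,
) -> tuple[LogisticRegression, np.ndarray, float, float]:
    """Fit the logistic combiner on layer-1 outputs.

    ``oof_outputs`` must be out-of-fold predictions (one row per training
    sample, columns HN and HL); supplying in-fold predictions without the
    explicit override raises, as that would leak the layer-1 training data
    into the stacker.
    """
    if not is_out_of_fold and not allow_in_fold:
        raise ValueError(
            "layer-1 outputs are not out-of-fold; pass allow_in_fold=True to override"
        )
    config = config or TrainConfig()
    grid = list(lambda_grid if lambda_grid is not None else config.lambda_grid)
    y = np.asarray(y)
    _check_two_classes(y, "train_stack")
    oof_outputs = np.asarray(oof_outputs, dtype=float)
    cv = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    search = GridSearchCV(
        LogisticRegression(solver="lbfgs", max_iter=1000),  # L2 penalty (default)
        {"C": [1.0 / lam for lam in grid]},
        scoring=config.scoring,
        cv=cv,
        n_jobs=1,
    )
    search.fit(oof_outputs, y)
    logistic = search.best_estimator_
    lam = 1.0 / logistic.C
    return logistic, logistic.coef_[0].copy(), float(logistic.intercept_[0]), float(lam)


def t_score(model: StackModel, X: pd.DataFrame) -> np.ndarray:
    """t-score h = w . (HN output, HL output) + b."""
    if model.w is None:
        raise ValueError("stack model is not fitted")
    return model.layer1_outputs(X) @ model.w + model.b


def predict_class(model: StackModel, h: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """HCC iff h >= threshold (boundary counts as HCC)."""
    thr = model.threshold if threshold is None else threshold
    return np.asarray(h) >= thr


def youden_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    """Score threshold maximizing sensitivity + specificity - 1."""
    fpr, tpr, thresholds = roc_curve(y, scores)
    return float(thresholds[np.argmax(tpr - fpr)])


@dataclass
class FoldRecord:
    fit_ids: list[str]
    val_ids: list[str]


@dataclass
class TrainingResult:
    stack: StackModel
    marker_union: list[str]
    oof_outputs: pd.DataFrame  # columns hn, hl, indexed by training sample id
    fold_records: list[FoldRecord]
    train_ids: list[str]
    test_ids: list[str]
    reports: dict


def _binary(labels: pd.Series) -> np.ndarray:
    return (labels == HCC).astype(int).to_numpy()


def _evaluate(h: np.ndarray, y: np.ndarray, threshold: float) -> dict:
    auc = roc_auc(h, y.astype(bool))
    pred = np.asarray(h) >= threshold
    counts = ConfusionCounts(
        tp=int((pred & (y == 1)).sum()),
        fp=int((pred & (y == 0)).sum()),
        tn=int((~pred & (y == 0)).sum()),
        fn=int((~pred & (y == 1)).sum()),
    )
    report = confusion_metrics(counts)
    report.update(
        auc=auc.auc,
        auc_ci=(auc.ci_low, auc.ci_high),
        threshold=threshold,
        n=len(y),
        counts=counts.__dict__,
    )
    return report


def run_full_training(cohort: Cohort, config: TrainConfig | None = None) -> TrainingResult:
    """End-to-end training and evaluation on a three-class cohort.

    1. Fit HN and HL (feature selection + hyperparameter search) on the
       relevant two-class subsets of the training split.
    2. Build out-of-fold layer-1 outputs by refitting both layer-1 estimators
       (fixed hyperparameters and feature lists) inside a stratified K-fold
       over the training split, predicting only the held-out fold.
    3. Fit the logistic combiner on those out-of-fold outputs; pick the
       decision threshold by Youden's J on the out-of-fold t-scores.
    4. Evaluate on the untouched test split.
    """
    config = config or TrainConfig()
    X_train = feature_frame(cohort.train, cohort.marker_names)
    labels_train = label_series(cohort.train)
    X_test = feature_frame(cohort.test, cohort.marker_names)
    labels_test = label_series(cohort.test)
    for split_labels, name in ((labels_train, "training"), (labels_test, "test")):
        missing = {"normal", "liver", HCC} - set(split_labels.unique())
        if missing:
            raise ValueError(f"{name} split lacks classes: {sorted(missing)}")

    hn_mask = labels_train.isin(["normal", HCC]).to_numpy()
    hl_mask = labels_train.isin(["liver", HCC]).to_numpy()
    y_hn = _binary(labels_train[hn_mask])
    y_hl = _binary(labels_train[hl_mask])
    logger.info("training HN model on %d samples", hn_mask.sum())
    hn = train_hn(X_train[hn_mask], y_hn, config)
    logger.info("HN model kept %d features; training HL model on %d samples",
                len(hn.features), hl_mask.sum())
    hl = train_hl(X_train[hl_mask], y_hl, config)

    # Out-of-fold layer-1 outputs over the full training split.
    oof = np.full((len(X_train), 2), np.nan)
    fold_records: list[FoldRecord] = []
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    ids = np.array(X_train.index)
    for fit_idx, val_idx in skf.split(X_train, labels_train):
        fold_records.append(FoldRecord(fit_ids=ids[fit_idx].tolist(), val_ids=ids[val_idx].tolist()))
        fit_labels = labels_train.iloc[fit_idx]
        for col, (layer, mask_labels) in enumerate(
            ((hn, ["normal", HCC]), (hl, ["liver", HCC]))
        ):
            sub = fit_labels.isin(mask_labels).to_numpy()
            rows = fit_idx[sub]
            est = clone(layer.estimator)
            est.fit(X_train.iloc[rows][layer.features], _binary(fit_labels[sub]))
            oof[val_idx, col] = est.predict_proba(X_train.iloc[val_idx][layer.features])[:, 1]

    y_train = _binary(labels_train)
    logistic, w, b, lam = train_stack(oof, y_train, config=config, is_out_of_fold=True)
    h_oof = oof @ w + b
    threshold = youden_threshold(h_oof, y_train)
    stack = StackModel(hn=hn, hl=hl, logistic=logistic, w=w, b=b, lam=lam,
                       threshold=threshold, fitted_on_oof=True)

    h_test = stack.t_score(X_test)
    marker_union = sorted(set(hn.features) | set(hl.features))
    reports = {
        "train_oof": _evaluate(h_oof, y_train, threshold),
        "test": _evaluate(h_test, _binary(labels_test), threshold),
        "n_markers": {
            "hn": len(hn.features),
            "hl": len(hl.features),
            "union": len(marker_union),
        },
        "lambda": lam,
    }
    return TrainingResult(
        stack=stack,
        marker_union=marker_union,
        oof_outputs=pd.DataFrame(oof, index=X_train.index, columns=["hn", "hl"]),
        fold_records=fold_records,
        train_ids=X_train.index.tolist(),
        test_ids=X_test.index.tolist(),
        reports=reports,
    )


def audit_no_leakage(result: TrainingResult) -> bool:
    """Verify the stacking protocol:

    * the combiner was fitted on out-of-fold outputs,
    * each training sample's layer-1 output came from a fold whose fit set
      excluded that sample,
    * the folds cover every training sample exactly once,
    * train and test sample ids are disjoint.

    Raises ``AssertionError`` on any violation; returns True otherwise.
    """
    assert result.stack.fitted_on_oof, "stacker was not fitted on out-of-fold outputs"
    covered: list[str] = []
    for rec in result.fold_records:
        overlap = set(rec.fit_ids) & set(rec.val_ids)
        assert not overlap, f"fold fit/val overlap: {sorted(overlap)[:3]}"
        covered.extend(rec.val_ids)
    assert sorted(covered) == sorted(result.train_ids), "folds do not partition the training set"
    assert not (set(result.train_ids) & set(result.test_ids)), "train/test sample overlap"
    assert not result.oof_outputs.isna().any().any(), "missing out-of-fold predictions"
    return True


MODEL_FORMAT_VERSION = 1


def save_model(stack: StackModel, path: str | Path) -> None:
    """Serialize a stack model as <path>.json (metadata) + <path>.joblib."""
    path = Path(path)
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "package_version": _pkg_version,
        "w": stack.w.tolist(),
        "b": stack.b,
        "lambda": stack.lam,
        "threshold": stack.threshold,
        "hn_features": stack.hn.features,
        "hl_features": stack.hl.features,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    joblib.dump(stack, path.with_suffix(".joblib"))


def load_model(path: str | Path) -> StackModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {meta['format_version']}")
    return joblib.load(path.with_suffix(".joblib"))
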