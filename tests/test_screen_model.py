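import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

from methylscreen.cohort_sim import CohortParams, simulate_cohort
from methylscreen.metrics_report import roc_auc
from methylscreen.screen_model import (
    StackModel,
    TrainConfig,
    audit_no_leakage,
    load_model,
    predict_class,
    run_full_training,
    save_model,
    t_score,
    train_hl,
    train_hn,
    train_stack,
    youden_threshold,
)

FAST = TrainConfig.fast(seed=0)


def _toy_features(n=80, n_noise=6, seed=0):
    """One perfectly separating feature plus noise columns."""
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = pd.DataFrame(
        rng.normal(size=(n, n_noise + 1)),
        columns=["signal"] + [f"noise{i}" for i in range(n_noise)],
    )
    X["signal"] = y + rng.normal(0, 0.01, size=n)
    return X, y


class _FixedLayer:
    """Stub layer-1 model returning a preset column of a frame."""

    def __init__(self, column):
        self.column = column
        self.features = [column]

    def predict(self, X):
        return X[self.column].to_numpy()


def _hand_stack(w, b, threshold=0.0):
    return StackModel(
        hn=_FixedLayer("hn_out"),
        hl=_FixedLayer("hl_out"),
        logistic=LogisticRegression(),
        w=np.asarray(w, dtype=float),
        b=b,
        lam=1.0,
        threshold=threshold,
        fitted_on_oof=True,
    )


class TestTrainHN:
    def test_separating_feature_retained_auc_one(self):
        X, y = _toy_features()
        model = train_hn(X, y, FAST)
        assert "signal" in model.features
        assert roc_auc(model.predict(X), y.astype(bool)).auc == 1.0

    def test_deterministic_feature_selection(self):
        X, y = _toy_features(seed=1)
        a = train_hn(X, y, FAST)
        b = train_hn(X, y, FAST)
        assert a.features == b.features

    def test_single_class_errors(self):
        X, _ = _toy_features()
        with pytest.raises(ValueError):
            train_hn(X, np.zeros(len(X), dtype=int), FAST)

    def test_pure_noise_cv_auc_near_half(self):
        rng = np.random.default_rng(42)
        X = pd.DataFrame(rng.normal(size=(200, 10)))
        y = rng.permutation([0, 1] * 100)
        est = GradientBoostingClassifier(
            n_estimators=50, max_depth=2, learning_rate=0.1, random_state=0
        )
        cv = StratifiedKFold(5, shuffle=True, random_state=0)
        auc = cross_val_score(est, X, y, cv=cv, scoring="roc_auc").mean()
        assert 0.35 <= auc <= 0.65


class TestTrainHL:
    def test_unused_feature_excluded(self):
        X, y = _toy_features()
        X["constant"] = 1.0  # never splittable -> zero importance
        model = train_hl(X, y, FAST)
        assert "constant" not in model.features
        assert "signal" in model.features

    def test_selected_set_matches_importance_scan(self):
        X, y = _toy_features(seed=3)
        model = train_hl(X, y, FAST)
        est = GradientBoostingClassifier(random_state=FAST.seed, **{
            k: v for k, v in model.best_params.items()
            if k in ("n_estimators", "max_depth", "learning_rate")
        })
        est.fit(X, y)
        expected = list(X.columns[est.feature_importances_ > 0])
        assert model.features == expected


class TestTrainStack:
    def _oof(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([0, 1] * (n // 2))
        oof = np.column_stack([y + rng.normal(0, 0.1, n), rng.normal(0, 1, n)])
        return oof, y

    def test_in_fold_without_override_errors(self):
        oof, y = self._oof()
        with pytest.raises(ValueError, match="out-of-fold"):
            train_stack(oof, y, config=FAST, is_out_of_fold=False)

    def test_in_fold_override_allowed(self):
        oof, y = self._oof()
        train_stack(oof, y, config=FAST, is_out_of_fold=False, allow_in_fold=True)

    def test_degenerate_constant_outputs_shrink_weights(self):
        y = np.array([0, 1] * 30)
        oof = np.full((60, 2), 0.5)
        logistic, w, b, _ = train_stack(oof, y, config=FAST)
        assert np.all(np.abs(w) < 1e-6)
        # prediction falls back to the class prior
        assert np.allclose(logistic.predict_proba(oof)[:, 1], 0.5, atol=0.01)

    def test_stacking_dominates_weak_layer(self):
        rng = np.random.default_rng(1)
        n = 200
        y = np.array([0, 1] * (n // 2))
        hn_out = y + rng.normal(0, 0.05, n)  # near-perfect
        hl_out = rng.normal(size=n)  # pure noise
        oof = np.column_stack([hn_out, hl_out])
        _, w, b, _ = train_stack(oof, y, config=FAST)
        h = oof @ w + b
        assert roc_auc(h, y.astype(bool)).auc >= roc_auc(hl_out, y.astype(bool)).auc


class TestTScore:
    def test_zero_weights_zero_score(self):
        stack = _hand_stack([0.0, 0.0], 0.0)
        X = pd.DataFrame({"hn_out": [0.3, 0.9], "hl_out": [0.1, 0.8]})
        assert np.allclose(t_score(stack, X), 0.0)

    def test_hand_arithmetic(self):
        stack = _hand_stack([2.0, 1.0], -1.0)
        X = pd.DataFrame({"hn_out": [0.5], "hl_out": [0.5]})
        assert t_score(stack, X) == pytest.approx([0.5])

    def test_doubling_weights_preserves_ordering(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"hn_out": rng.random(20), "hl_out": rng.random(20)})
        a = t_score(_hand_stack([0.7, 0.3], 0.1), X)
        b = t_score(_hand_stack([1.4, 0.6], 0.2), X)
        assert list(np.argsort(a)) == list(np.argsort(b))


class TestPredictClass:
    def test_boundary_is_positive(self):
        stack = _hand_stack([1.0, 0.0], 0.0, threshold=0.5)
        assert predict_class(stack, np.array([0.5]))[0]
        assert not predict_class(stack, np.array([0.499]))[0]

    def test_threshold_sweep_traces_roc(self):
        rng = np.random.default_rng(3)
        h = rng.normal(size=100)
        y = (h + rng.normal(0, 1, 100)) > 0
        stack = _hand_stack([1.0, 0.0], 0.0)
        # sweep every achievable threshold and integrate the empirical ROC
        thresholds = np.concatenate([[np.inf], np.sort(h)[::-1]])
        tpr = [np.mean(predict_class(stack, h, t)[y]) for t in thresholds]
        fpr = [np.mean(predict_class(stack, h, t)[~y]) for t in thresholds]
        swept_auc = np.trapezoid(tpr, fpr)
        assert swept_auc == pytest.approx(roc_auc(h, y).auc)


class TestYoudenThreshold:
    def test_separable_case(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        thr = youden_threshold(scores, y)
        pred = scores >= thr
        assert (pred == y.astype(bool)).all()


SMALL_COHORT = CohortParams(
    n_train=(40, 15, 40), n_test=(20, 8, 20), n_markers=40, seed=21
)


@pytest.fixture(scope="module")
def result():
    return run_full_training(simulate_cohort(SMALL_COHORT), TrainConfig.fast(seed=21))


class TestRunFullTraining:

    def test_report_structure(self, result):
        assert {"train_oof", "test", "n_markers", "lambda"} <= set(result.reports)
        assert result.reports["n_markers"]["union"] == len(result.marker_union)

    def test_deterministic_repeat(self, result):
        again = run_full_training(simulate_cohort(SMALL_COHORT), TrainConfig.fast(seed=21))
        assert again.reports["test"] == result.reports["test"]
        assert again.marker_union == result.marker_union

    def test_audit_passes(self, result):
        assert audit_no_leakage(result)

    def test_missing_class_errors(self):
        params = CohortParams(n_train=(40, 0, 40), n_test=(10, 5, 10), n_markers=20, seed=2)
        with pytest.raises(ValueError, match="lacks classes"):
            run_full_training(simulate_cohort(params), TrainConfig.fast())

    def test_model_round_trip(self, result, tmp_path):
        save_model(result.stack, tmp_path / "model")
        loaded = load_model(tmp_path / "model")
        cohort = simulate_cohort(SMALL_COHORT)
        from methylscreen.cohort_sim import feature_frame

        X = feature_frame(cohort.test, cohort.marker_names)
        assert np.allclose(loaded.t_score(X), result.stack.t_score(X))
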