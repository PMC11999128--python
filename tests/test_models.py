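"""Nested transition models: tasks, datasets, resampling, metrics,
kappa cutoffs, marginal effects and the stage-probability calculator."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from dmtransit.models import (
    BINARY_FEATURES,
    DegenerateDataError,
    EmptyTaskError,
    FEATURES,
    FitResult,
    ModelTask,
    OUTCOME_COMPLICATION,
    OUTCOME_OUT_GOAL,
    ResamplingError,
    TrainConfig,
    build_tasks,
    kappa_optimal_cutoff,
    make_dataset,
    marginal_effects,
    metrics,
    predict_stage_probabilities,
    resample,
    select_features,
    train_and_select,
)
from dmtransit.neural import FeedForwardClassifier
from dmtransit.stages import Stage


class TestBuildTasks:
    def test_twelve_tasks(self):
        assert len(build_tasks()) == 12

    def test_per_horizon_structure(self):
        tasks = build_tasks()
        for horizon in (1, 2):
            horizon_tasks = [t for t in tasks if t.horizon == horizon]
            goal = [t for t in horizon_tasks if t.outcome == OUTCOME_OUT_GOAL]
            comp = [t for t in horizon_tasks if t.outcome == OUTCOME_COMPLICATION]
            assert len(goal) == 4 and len(comp) == 2

    def test_no_complication_task_for_complicated_starters(self):
        tasks = build_tasks()
        assert not any(
            t.outcome == OUTCOME_COMPLICATION and t.initial_stage.has_complication
            for t in tasks
        )
        with pytest.raises(ValueError, match="absorbing"):
            ModelTask(1, Stage.ON_YES, OUTCOME_COMPLICATION)


def _hand_staged():
    """Six patients, three years, hand-readable stages and features."""
    rows = []
    paths = {
        0: ["ON-NOT", "OUT-NOT", "OUT-YES"],
        1: ["ON-NOT", "ON-NOT", "ON-NOT"],
        2: ["ON-NOT", "ON-YES", "ON-YES"],
        3: ["OUT-NOT", "OUT-NOT", "OUT-NOT"],
        4: ["ON-NOT", "ON-NOT", "OUT-NOT"],
        5: ["OUT-NOT", "ON-NOT", "ON-NOT"],
    }
    for pid, path in paths.items():
        for year, stage in zip((2018, 2019, 2020), path):
            rows.append(
                {
                    "patient_id": pid,
                    "year": year,
                    "stage": stage,
                    "age": 60 + pid,
                    "sex": "F" if pid % 2 else "M",
                    "hba1c": 7.0,
                    "ldl_cholesterol": 95.0,
                    "egfr": 80.0,
                    "creatinine": 0.9,
                    "bmi": 28.0,
                    "weight": 75.0,
                    "height": 1.6,
                    "diastolic_bp": 75.0,
                    "systolic_bp": 122.0,
                    "drugs": "metformin",
                    "adherence": "unstated",
                    "hba1c_guide": True,
                    "cholesterol_guide": False,
                    "rec_nutrition": True,
                    "rec_physical": False,
                    "rec_alcohol": False,
                    "rec_tobacco": False,
                    "referral_ophthalmology": False,
                }
            )
    return pd.DataFrame(rows)


class TestMakeDataset:
    def test_hand_traced_labels(self):
        staged = _hand_staged()
        X, y = make_dataset(staged, ModelTask(1, Stage.ON_NOT, OUTCOME_OUT_GOAL))
        # ON-NOT baselines: p0@2018, p1@2018, p1@2019, p2@2018, p4@2018,
        # p4@2019, p5@2019 -> OUT next year: p0 yes, p4@2019 yes, rest no
        labels = dict(zip(X.index, y))
        assert labels[(0, 2018)] == 1
        assert labels[(4, 2019)] == 1
        assert labels[(1, 2018)] == 0
        assert sum(labels.values()) == 2

    def test_complication_outcome_labels(self):
        staged = _hand_staged()
        X, y = make_dataset(staged, ModelTask(1, Stage.ON_NOT, OUTCOME_COMPLICATION))
        labels = dict(zip(X.index, y))
        assert labels[(2, 2018)] == 1  # develops a complication
        assert labels[(1, 2018)] == 0

    def test_empty_initial_condition_errors(self):
        staged = _hand_staged()
        with pytest.raises(EmptyTaskError, match="ON-YES"):
            make_dataset(staged, ModelTask(2, Stage.ON_YES, OUTCOME_OUT_GOAL))

    def test_no_leakage_columns(self):
        X, _ = make_dataset(_hand_staged(), ModelTask(1, Stage.ON_NOT, OUTCOME_OUT_GOAL))
        assert list(X.columns) == FEATURES
        assert not any("stage" in c or "horizon" in c for c in X.columns)


class TestSelectFeatures:
    def test_constant_column_dropped(self, rng):
        X = pd.DataFrame({"constant": np.ones(50), "varying": rng.normal(size=50)})
        assert list(select_features(X).columns) == ["varying"]

    def test_duplicated_column_dropped_once(self, rng):
        base = rng.normal(size=80)
        X = pd.DataFrame({"a": base, "b": base.copy(), "c": rng.normal(size=80)})
        kept = list(select_features(X).columns)
        assert kept == ["a", "c"]

    def test_planted_informative_feature_retained(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 300
            signal = r.normal(size=n)
            y = (signal + 0.3 * r.normal(size=n) > 0).astype(int)
            X = pd.DataFrame({"signal": signal})
            for j in range(8):
                X[f"noise{j}"] = r.normal(size=n)
            kept = select_features(X, pd.Series(y), top_k=3, seed=seed)
            hits += "signal" in kept.columns
        assert hits >= 9

    def test_all_dropped_errors(self):
        X = pd.DataFrame({"a": np.ones(10), "b": np.zeros(10)})
        with pytest.raises(Exception, match="variance"):
            select_features(X)


class TestResample:
    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.array([0, 1] * 20)
        X2, y2 = resample(X, y, "upsample_minority", seed=0)
        assert len(y2) == 40

    def test_upsample_minority_reaches_majority(self, rng):
        X = rng.normal(size=(1000, 4))
        y = np.array([0] * 900 + [1] * 100)
        _, y2 = resample(X, y, "upsample_minority", seed=0)
        assert (y2 == 0).sum() == 900 and (y2 == 1).sum() == 900

    def test_intermediate_strategy_sizes(self, rng):
        X = rng.normal(size=(1000, 4))
        y = np.array([0] * 900 + [1] * 100)
        _, y2 = resample(X, y, "upsample_and_downsample", seed=0)
        assert (y2 == 0).sum() == 500 and (y2 == 1).sum() == 500

    def test_synthetic_points_on_minority_segments(self, rng):
        """Geometric oracle: every synthetic point is a convex combination
        of two minority points (collinear and between them)."""
        minority = rng.normal(size=(20, 2))
        X = np.vstack([minority, rng.normal(5, 1, size=(60, 2))])
        y = np.array([1] * 20 + [0] * 60)
        X2, y2 = resample(X, y, "upsample_minority", seed=3)
        synthetic = X2[:40][~(X2[:40][:, None] == minority[None]).all(-1).any(-1)]
        for point in synthetic:
            on_segment = False
            for i in range(20):
                for j in range(20):
                    if i == j:
                        continue
                    a, b = minority[i], minority[j]
                    d = np.linalg.norm(a - b)
                    if d < 1e-12:
                        continue
                    gap = np.linalg.norm(a - point) + np.linalg.norm(point - b) - d
                    if gap < 1e-8:
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_tiny_minority_errors(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.array([0] * 17 + [1] * 3)
        with pytest.raises(ResamplingError, match="smaller k"):
            resample(X, y, "upsample_minority", seed=0, k_neighbors=5)

    def test_input_arrays_not_mutated(self, rng):
        X = rng.normal(size=(100, 3))
        y = np.array([0] * 80 + [1] * 20)
        X_copy, y_copy = X.copy(), y.copy()
        resample(X, y, "upsample_and_downsample", seed=0)
        assert np.array_equal(X, X_copy) and np.array_equal(y, y_copy)


class TestMetrics:
    def test_perfect_probabilities(self):
        y = [0, 0, 1, 1]
        m = metrics(y, [0.1, 0.2, 0.8, 0.9], cutoff=0.5)
        for key in ("accuracy", "f1", "auc", "tpr", "tnr"):
            assert m[key] == 1.0

    def test_hand_confusion_counts(self):
        # TP=3 FP=1 FN=1 TN=5
        y = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        p = [0.9, 0.8, 0.7, 0.2, 0.6, 0.1, 0.1, 0.1, 0.1, 0.1]
        m = metrics(y, p, cutoff=0.5)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["f1"] == pytest.approx(0.75)

    def test_tied_probabilities_auc_half(self):
        m = metrics([0, 1, 0, 1], [0.5] * 4)
        assert m["auc"] == pytest.approx(0.5)

    def test_rates_sum_to_one(self, rng):
        y = rng.integers(0, 2, size=100)
        p = rng.random(100)
        m = metrics(y, p, cutoff=0.4)
        assert m["tpr"] + m["fnr"] == pytest.approx(1.0)
        assert m["tnr"] + m["fpr"] == pytest.approx(1.0)

    def test_single_class_auc_flagged(self):
        m = metrics([1, 1, 1], [0.2, 0.5, 0.9])
        assert m["auc_undefined"] and np.isnan(m["auc"])

    def test_auc_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, size=200)
        p = rng.random(200)
        auc1 = metrics(y, p)["auc"]
        auc2 = metrics(y, np.sqrt(p))["auc"]
        assert auc1 == pytest.approx(auc2, abs=1e-12)


def brute_force_kappa_max(y, p):
    """Independent oracle: Cohen's kappa from its definition, evaluated on
    a dense threshold grid plus all observed probabilities."""
    y = np.asarray(y)
    thresholds = np.unique(np.concatenate([np.linspace(0, 1, 2001), p]))
    best = -np.inf
    for t in thresholds:
        pred = (np.asarray(p) >= t).astype(int)
        po = (pred == y).mean()
        pe = ((pred == 1).mean() * (y == 1).mean()) + ((pred == 0).mean() * (y == 0).mean())
        kappa = 0.0 if pe == 1.0 else (po - pe) / (1 - pe)
        best = max(best, kappa)
    return best


class TestKappaOptimalCutoff:
    def test_separated_probabilities(self):
        y = [0, 0, 1, 1]
        p = [0.1, 0.2, 0.8, 0.9]
        cutoff = kappa_optimal_cutoff(y, p)
        assert cutoff == pytest.approx(0.5)  # smallest maximizing midpoint
        assert metrics(y, p, cutoff)["accuracy"] == 1.0

    def test_eight_point_hand_example(self):
        y = [0, 0, 0, 1, 0, 1, 1, 1]
        p = [0.05, 0.2, 0.35, 0.4, 0.5, 0.6, 0.8, 0.95]
        cutoff = kappa_optimal_cutoff(y, p)
        from sklearn.metrics import cohen_kappa_score

        achieved = cohen_kappa_score(y, (np.array(p) >= cutoff).astype(int))
        assert achieved == pytest.approx(brute_force_kappa_max(y, p), abs=1e-9)

    def test_matches_brute_force_on_random_instances(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(100):
            n = int(rng.integers(4, 200))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            p = np.round(rng.random(n), 3)
            cutoff = kappa_optimal_cutoff(y, p)
            achieved = cohen_kappa_score(y, (p >= cutoff).astype(int))
            assert achieved == pytest.approx(brute_force_kappa_max(y, p), abs=1e-9)

    def test_independent_labels_near_zero_kappa(self, rng):
        y = rng.integers(0, 2, size=3000)
        p = rng.random(3000)
        from sklearn.metrics import cohen_kappa_score

        cutoff = kappa_optimal_cutoff(y, p)
        assert cohen_kappa_score(y, (p >= cutoff).astype(int)) < 0.1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            kappa_optimal_cutoff([1, 1], [0.2, 0.8])


def _separable_data(n=200, seed=0):
    r = np.random.default_rng(seed)
    x = r.normal(size=(n, 3))
    y = (x[:, 0] > 0).astype(int)
    x[:, 0] += np.where(y == 1, 3.0, -3.0)
    return pd.DataFrame(x, columns=["a", "b", "c"]), pd.Series(y)


class TestTrainAndSelect:
    def test_separable_task_perfect_f1(self):
        X, y = _separable_data()
        fit = train_and_select(X, y, TrainConfig.fast(seed=0))
        assert fit.test_metrics["f1"] == 1.0

    def test_single_class_rejected(self):
        X, _ = _separable_data()
        with pytest.raises(DegenerateDataError):
            train_and_select(X, pd.Series(np.ones(len(X), dtype=int)), TrainConfig.fast())

    def test_deterministic_given_seed(self):
        X, y = _separable_data(seed=5)
        fit1 = train_and_select(X, y, TrainConfig.fast(seed=3))
        fit2 = train_and_select(X, y, TrainConfig.fast(seed=3))
        assert fit1.test_metrics == fit2.test_metrics
        assert fit1.cutoff == fit2.cutoff
        pd.testing.assert_series_equal(fit1.marginal_effects, fit2.marginal_effects)

    def test_logistic_dgp_logistic_competitive(self):
        """On data generated by a logistic model the logistic family's CV F1
        is within noise of the best candidate."""
        r = np.random.default_rng(2)
        n = 600
        X = pd.DataFrame(r.normal(size=(n, 4)), columns=list("abcd"))
        logits = 1.5 * X["a"] - 1.0 * X["b"]
        y = pd.Series((r.random(n) < 1 / (1 + np.exp(-logits))).astype(int))
        config = TrainConfig(
            families=("logistic", "decision_tree", "knn"),
            grids={
                "logistic": [{"C": 1.0}],
                "decision_tree": [{"max_depth": 5}],
                "knn": [{"n_neighbors": 15}],
            },
            cv_folds=5,
            seed=0,
        )
        fit = train_and_select(X, y, config)
        cv = fit.cv_results.set_index("family")["cv_f1"]
        assert cv["logistic"] >= cv.max() - 0.05

    def test_full_grid_runs_on_one_task(self):
        """Every learner family in the default grid trains and scores."""
        X, y = _separable_data(n=120, seed=1)
        config = TrainConfig(
            grids={k: v[:1] for k, v in TrainConfig().grids.items()},
            cv_folds=3,
            seed=0,
        )
        config = TrainConfig(
            families=config.families, grids=config.grids, cv_folds=3, seed=0
        )
        fit = train_and_select(X, y, config)
        assert set(fit.cv_results["family"]) == set(TrainConfig().families)
        assert fit.test_metrics["f1"] > 0.9

    def test_smote_variant_trains(self):
        r = np.random.default_rng(4)
        n = 400
        X = pd.DataFrame(r.normal(size=(n, 3)), columns=list("abc"))
        y = pd.Series((X["a"] + r.normal(scale=2.0, size=n) > 1.8).astype(int))
        fit = train_and_select(X, y, TrainConfig.fast(seed=0, resampling="upsample_minority"))
        assert 0.0 <= fit.test_metrics["f1"] <= 1.0


class TestFeedForward:
    def test_probabilities_in_open_interval(self, rng):
        X = rng.normal(size=(50, 4))
        y = rng.integers(0, 2, size=50)
        net = FeedForwardClassifier(epochs=2, random_state=0).fit(X, y)
        p = net.predict_proba(rng.normal(size=(20, 4)))[:, 1]
        assert ((p > 0) & (p < 1)).all()

    def test_xor_pattern_learned(self):
        r = np.random.default_rng(0)
        X = r.uniform(-1, 1, size=(600, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        net = FeedForwardClassifier(epochs=60, learning_rate=1e-3, random_state=0)
        net.fit(X, y)
        assert (net.predict(X) == y).mean() > 0.9

    def test_dropout_one_rejected(self, rng):
        net = FeedForwardClassifier(dropout=1.0)
        with pytest.raises(ValueError, match="dropout"):
            net.fit(rng.normal(size=(10, 2)), rng.integers(0, 2, size=10))


class _IgnoringModel:
    """Probability depends only on column 0."""

    def predict_proba(self, X):
        p = 1 / (1 + np.exp(-X[:, 0]))
        return np.column_stack([1 - p, p])


class TestMarginalEffects:
    def test_ignored_feature_zero_effect(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 2)), columns=["used", "ignored"])
        effects = marginal_effects(_IgnoringModel(), X)
        assert effects["ignored"] == 0.0
        assert effects["used"] != 0.0

    def test_matches_logistic_closed_form(self, rng):
        """For a binary feature with coefficient beta the effect equals the
        averaged closed-form probability difference."""
        n = 300
        X = pd.DataFrame(
            {"binary": rng.integers(0, 2, size=n).astype(float),
             "cont": rng.normal(size=n)}
        )
        beta0, beta_b, beta_c = -0.3, 0.8, 0.5
        logits = beta0 + beta_b * X["binary"] + beta_c * X["cont"]
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        model = LogisticRegression(C=1e6).fit(X.to_numpy(), y)
        effects = marginal_effects(model, X)
        b0 = model.intercept_[0]
        b = model.coef_[0]
        p1 = 1 / (1 + np.exp(-(b0 + b[0] * 1 + b[1] * X["cont"])))
        p0 = 1 / (1 + np.exp(-(b0 + b[0] * 0 + b[1] * X["cont"])))
        assert effects["binary"] == pytest.approx(100 * (p1 - p0).mean(), abs=1e-6)


class TestPredictStageProbabilities:
    @staticmethod
    def _stub_fit(p):
        class _Const:
            def predict_proba(self, X):
                return np.column_stack([np.full(len(X), 1 - p), np.full(len(X), p)])

        return FitResult(
            task=None, family="stub", params={}, cv_results=pd.DataFrame(),
            cutoff=0.5, train_metrics={}, test_metrics={},
            marginal_effects=pd.Series(dtype=float), model=_Const(),
            feature_names=["age"],
        )

    def _bundle(self, p_out, p_comp):
        return {
            ModelTask(1, Stage.ON_NOT, OUTCOME_OUT_GOAL).key: self._stub_fit(p_out),
            ModelTask(1, Stage.ON_NOT, OUTCOME_COMPLICATION).key: self._stub_fit(p_comp),
            ModelTask(1, Stage.ON_YES, OUTCOME_OUT_GOAL).key: self._stub_fit(p_out),
        }

    def test_independence_product(self):
        vector = predict_stage_probabilities(
            self._bundle(0.3, 0.4), {"age": 60}, 1, Stage.ON_NOT
        )
        assert vector.tolist() == pytest.approx([0.42, 0.18, 0.28, 0.12])

    def test_complication_starter_structural_zeros(self):
        vector = predict_stage_probabilities(
            self._bundle(0.3, 0.4), {"age": 60}, 1, Stage.ON_YES
        )
        assert vector["ON-NOT"] == 0.0 and vector["OUT-NOT"] == 0.0
        assert vector.sum() == pytest.approx(1.0)

    def test_vector_sums_to_one(self, rng):
        for _ in range(10):
            p_out, p_comp = rng.random(), rng.random()
            vector = predict_stage_probabilities(
                self._bundle(p_out, p_comp), {"age": 60}, 1, Stage.ON_NOT
            )
            assert vector.sum() == pytest.approx(1.0)

    def test_missing_feature_listed(self):
        from dmtransit.models import MissingFeatureError

        with pytest.raises(MissingFeatureError, match="age"):
            predict_stage_probabilities(self._bundle(0.3, 0.4), {}, 1, Stage.ON_NOT)
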