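"""Nested binary transition-prediction models.

The four-stage, two-horizon prediction problem is decomposed into
twelve binary tasks: for each horizon (1 and 2 years) and each initial
stage, one model predicts being OUT of HbA1c goals at the horizon, and
— for the two no-complication initial stages only, since complications
are absorbing — a second model predicts developing a complication.

Each task is fitted by a grid search over learner families
(K-nearest-neighbors, logistic regression, decision tree, random
forest, gradient/adaptive/light-gradient boosting, extra trees, and a
3x256 ReLU feed-forward network) with stratified k-fold
cross-validation, optional SMOTE-style resampling of the training folds
only, and selection by mean CV F1 (ties broken by AUC, then accuracy).
The selected model's predicted probabilities are binarized at the
cutoff that maximizes Cohen's kappa, and per-feature marginal effects
on the predicted transition probability are reported in percentage
points. The two binary models of a no-complication starter are combined
into a 4-stage probability vector under an independence assumption.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import cohen_kappa_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .adherence import drug_class, expand_combinations
from .neural import FeedForwardClassifier
from .stages import STAGE_ORDER, Stage

OUTCOME_OUT_GOAL = "out_goal"
OUTCOME_COMPLICATION = "complication"


@dataclass(frozen=True)
class ModelTask:
    """One of the twelve nested binary prediction problems."""

    horizon: int
    initial_stage: Stage
    outcome: str

    def __post_init__(self) -> None:
        if self.horizon not in (1, 2):
            raise ValueError(f"horizon must be 1 or 2, got {self.horizon}")
        if self.outcome not in (OUTCOME_OUT_GOAL, OUTCOME_COMPLICATION):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.outcome == OUTCOME_COMPLICATION and self.initial_stage.has_complication:
            raise ValueError(
                "complication outcome undefined for complication starters "
                "(the state is absorbing)"
            )

    @property
    def key(self) -> str:
        return f"{self.horizon}y|{self.initial_stage.value}|{self.outcome}"


def build_tasks() -> list[ModelTask]:
    """All twelve tasks: per horizon, a goal-outcome model for each of
    the four stages plus complication-outcome models for the two
    no-complication stages."""
    tasks = []
    for horizon in (1, 2):
        for stage in STAGE_ORDER:
            tasks.append(ModelTask(horizon, stage, OUTCOME_OUT_GOAL))
        for stage in (Stage.ON_NOT, Stage.OUT_NOT):
            tasks.append(ModelTask(horizon, stage, OUTCOME_COMPLICATION))
    return tasks


# ---------------------------------------------------------------------------
# feature engineering

CONTINUOUS_FEATURES = [
    "age",
    "ldl_cholesterol",
    "egfr",
    "creatinine",
    "bmi",
    "weight",
    "height",
    "diastolic_bp",
    "systolic_bp",
    "hba1c",
    "n_antihypertensive",
    "n_hypoglycemic",
    "n_lipid_lowering",
]
BINARY_FEATURES = [
    "female",
    "analgesic",
    "antacid",
    "non_compliant",
    "hba1c_guide",
    "cholesterol_guide",
    "rec_nutrition",
    "rec_physical",
    "rec_alcohol",
    "rec_tobacco",
    "referral_ophthalmology",
]
FEATURES = CONTINUOUS_FEATURES + BINARY_FEATURES


def _drug_counts(drugs: Sequence[str]) -> dict[str, float]:
    expanded = expand_combinations(drugs)
    classes = [drug_class(d) for d in expanded]
    return {
        "n_antihypertensive": classes.count("antihypertensive"),
        "n_hypoglycemic": classes.count("hypoglycemic_first_line")
        + classes.count("hypoglycemic_second_line")
        + classes.count("insulin"),
        "n_lipid_lowering": classes.count("lipid_lowering"),
        "analgesic": float(any(c == "analgesic" for c in classes)),
        "antacid": float(any(c == "antacid" for c in classes)),
    }


def build_feature_frame(labeled: pd.DataFrame) -> pd.DataFrame:
    """Baseline feature matrix from a labeled, staged cohort table.

    Expects the merged table produced by the pipeline's labeling step:
    structured biomarkers plus the NLP-derived ``drugs``, ``adherence``,
    recommendation and guideline-adherence columns. Returns one row per
    patient-year with the model feature set, indexed by
    ``(patient_id, year)``.
    """
    frame = labeled.set_index(["patient_id", "year"]).copy()
    out = pd.DataFrame(index=frame.index)
    for col in (
        "age",
        "ldl_cholesterol",
        "egfr",
        "creatinine",
        "bmi",
        "weight",
        "height",
        "diastolic_bp",
        "systolic_bp",
        "hba1c",
    ):
        out[col] = pd.to_numeric(frame[col], errors="coerce")
    out["female"] = (frame["sex"] == "F").astype(float)
    drug_lists = frame["drugs"].map(
        lambda v: [d for d in str(v).split(";") if d] if pd.notna(v) else []
    )
    counts = pd.DataFrame([_drug_counts(d) for d in drug_lists], index=frame.index)
    out = out.join(counts)
    out["non_compliant"] = (frame["adherence"] == "non_compliant").astype(float)
    for col in (
        "hba1c_guide",
        "cholesterol_guide",
        "rec_nutrition",
        "rec_physical",
        "rec_alcohol",
        "rec_tobacco",
        "referral_ophthalmology",
    ):
        out[col] = frame[col].astype(bool).astype(float) if col in frame else 0.0
    return out[FEATURES]


class EmptyTaskError(ValueError):
    pass


def make_dataset(
    staged: pd.DataFrame, task: ModelTask
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature matrix and binary labels for one prediction task.

    Rows are patient-years whose stage equals the task's initial
    condition and whose stage ``horizon`` years later is observed; all
    baseline year pairs present in the panel are pooled. Features come
    from the baseline year only — nothing measured at the horizon leaks
    into the matrix.
    """
    features = build_feature_frame(staged)
    stages = staged.set_index(["patient_id", "year"])["stage"].dropna()
    rows: list[tuple] = []
    labels: list[int] = []
    years = sorted({y for _, y in stages.index})
    for y0 in years:
        y1 = y0 + task.horizon
        if y1 not in years:
            continue
        at_y0 = stages.xs(y0, level="year")
        at_y1 = stages.xs(y1, level="year")
        eligible = at_y0[at_y0 == task.initial_stage.value].index.intersection(
            at_y1.index
        )
        for pid in eligible:
            end_stage = Stage(at_y1.loc[pid])
            if task.outcome == OUTCOME_OUT_GOAL:
                labels.append(int(not end_stage.on_goal))
            else:
                labels.append(int(end_stage.has_complication))
            rows.append((pid, y0))
    if not rows:
        raise EmptyTaskError(
            f"no patients in initial condition {task.initial_stage.value} "
            f"with horizon {task.horizon}"
        )
    X = features.loc[rows]
    y = pd.Series(labels, index=X.index, name="label")
    mask = X.notna().all(axis=1)
    return X[mask], y[mask]


# ---------------------------------------------------------------------------
# feature selection

try:  # lightgbm emits sklearn-version warnings on import in some builds
    from lightgbm import LGBMClassifier
except ImportError:  # pragma: no cover
    LGBMClassifier = None


class AllFeaturesDroppedError(ValueError):
    pass


def select_features(
    X: pd.DataFrame,
    y: pd.Series | None = None,
    *,
    variance_threshold: float = 1e-8,
    correlation_threshold: float = 0.95,
    top_k: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Drop low-variance then collinear columns, then keep top-k by
    boosted-tree importance.

    Of a correlated pair the later column (in frame order) is dropped.
    The importance ranking runs a light-gradient-boosting model when
    ``top_k`` is given and labels are supplied. Deterministic given the
    seed.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    keep = [c for c in X.columns if float(np.var(X[c].to_numpy())) > variance_threshold]
    if not keep:
        raise AllFeaturesDroppedError("all columns have (near-)zero variance")
    X = X[keep]
    if X.shape[1] > 1:
        corr = X.corr().abs().to_numpy()
        drop: set[int] = set()
        for i in range(len(keep)):
            if i in drop:
                continue
            for j in range(i + 1, len(keep)):
                if j not in drop and corr[i, j] > correlation_threshold:
                    drop.add(j)
        keep = [c for idx, c in enumerate(keep) if idx not in drop]
        X = X[keep]
    if top_k is not None and y is not None and X.shape[1] > top_k:
        model = LGBMClassifier(
            n_estimators=100, random_state=seed, verbose=-1, n_jobs=1,
            min_child_samples=5,
        )
        model.fit(X.to_numpy(), np.asarray(y))
        importance = pd.Series(model.feature_importances_, index=X.columns)
        keep = list(importance.sort_values(ascending=False, kind="stable").index[:top_k])
        X = X[[c for c in X.columns if c in set(keep)]]
    if X.shape[1] == 0:
        raise AllFeaturesDroppedError("feature selection removed every column")
    return X


# ---------------------------------------------------------------------------
# resampling (SMOTE-style)

RESAMPLING_STRATEGIES = ("none", "upsample_minority", "upsample_and_downsample")


class ResamplingError(ValueError):
    pass


def _smote_points(
    minority: np.ndarray, n_new: int, k_neighbors: int, rng: np.random.Generator
) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(minority)
    _, neighbor_idx = nn.kneighbors(minority)
    base = rng.integers(len(minority), size=n_new)
    picked = neighbor_idx[base, rng.integers(1, k_neighbors + 1, size=n_new)]
    u = rng.random((n_new, 1))
    return minority[base] + u * (minority[picked] - minority[base])


def resample(
    X,
    y,
    strategy: str = "upsample_minority",
    seed: int = 0,
    *,
    k_neighbors: int = 5,
    intermediate_size: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance a binary training set with synthetic minority oversampling.

    ``upsample_minority`` raises the minority class to the majority
    count (majority untouched). ``upsample_and_downsample`` moves both
    classes to an intermediate size (default: the rounded mean of the
    two class counts), downsampling the majority without replacement.
    Synthetic points are convex combinations of a minority point and
    one of its ``k_neighbors`` nearest minority neighbors. Apply to
    training folds only — never to a held-out split.
    """
    if strategy not in RESAMPLING_STRATEGIES:
        raise ResamplingError(f"unknown strategy {strategy!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if strategy == "none":
        return X, y
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ResamplingError("resampling requires exactly two classes")
    rng = np.random.default_rng(seed)
    minority_cls = classes[np.argmin(counts)]
    majority_cls = classes[np.argmax(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return X, y
    if n_min < k_neighbors + 1:
        raise ResamplingError(
            f"minority class has {n_min} points; need more than k_neighbors="
            f"{k_neighbors} — use a smaller k"
        )
    minority = X[y == minority_cls]
    majority = X[y == majority_cls]
    if strategy == "upsample_minority":
        target_min, target_maj = n_maj, n_maj
    else:
        target = intermediate_size or int(round((n_min + n_maj) / 2))
        target_min, target_maj = target, target
    synthetic = _smote_points(minority, target_min - n_min, k_neighbors, rng)
    if target_maj < n_maj:
        keep = rng.choice(n_maj, size=target_maj, replace=False)
        majority = majority[keep]
    X_out = np.vstack([minority, synthetic, majority])
    y_out = np.concatenate(
        [
            np.full(target_min, minority_cls),
            np.full(len(majority), majority_cls),
        ]
    )
    return X_out, y_out


# ---------------------------------------------------------------------------
# metrics and cutoff

def metrics(labels, probabilities, cutoff: float = 0.5) -> dict[str, float]:
    """Accuracy, F1 (positive class), rank AUC and confusion rates."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    pred = (p >= cutoff).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    accuracy = (tp + tn) / len(y)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    if len(np.unique(y)) < 2:
        auc, auc_undefined = float("nan"), True
    else:
        auc, auc_undefined = float(roc_auc_score(y, p)), False
    pos, neg = tp + fn, tn + fp
    return {
        "accuracy": accuracy,
        "f1": f1,
        "auc": auc,
        "auc_undefined": auc_undefined,
        "tpr": tp / pos if pos else float("nan"),
        "fnr": fn / pos if pos else float("nan"),
        "tnr": tn / neg if neg else float("nan"),
        "fpr": fp / neg if neg else float("nan"),
        "cutoff": cutoff,
    }


def kappa_optimal_cutoff(labels, probabilities) -> float:
    """Probability cutoff maximizing Cohen's kappa.

    Candidates are 0, 1 and every midpoint between adjacent distinct
    sorted probabilities (a prediction is positive when the probability
    is at or above the cutoff). Ties resolve to the smallest cutoff.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to optimize kappa")
    distinct = np.unique(p)
    candidates = np.concatenate([[0.0], (distinct[:-1] + distinct[1:]) / 2, [1.0]])
    best_cutoff, best_kappa = 0.0, -np.inf
    for cutoff in candidates:
        kappa = cohen_kappa_score(y, (p >= cutoff).astype(int))
        if kappa > best_kappa + 1e-12:
            best_kappa, best_cutoff = kappa, float(cutoff)
    return best_cutoff


# ---------------------------------------------------------------------------
# model grid

SCALED_FAMILIES = {"knn", "logistic", "feedforward"}

DEFAULT_GRIDS: dict[str, list[dict]] = {
    "knn": [{"n_neighbors": k} for k in (5, 15, 31)],
    "logistic": [{"C": c} for c in (0.1, 1.0, 10.0)],
    "decision_tree": [{"max_depth": d} for d in (3, 5, 10)],
    "random_forest": [{"n_estimators": 100, "max_depth": d} for d in (5, 10)],
    "gradient_boosting": [{"n_estimators": n} for n in (50, 200)],
    "ada_boost": [{"n_estimators": n} for n in (50, 200)],
    "lightgbm": [{"n_estimators": n} for n in (50, 200)],
    "extra_trees": [{"n_estimators": 100}],
    "feedforward": [
        {"l2": l2, "learning_rate": lr, "epochs": ep}
        for l2, lr, ep in itertools.product((1e-4, 1e-3), (1e-3, 1e-2), (20, 50))
    ],
}


def make_estimator(family: str, params: Mapping, seed: int):
    params = dict(params)
    if family == "knn":
        est = KNeighborsClassifier(**params)
    elif family == "logistic":
        est = LogisticRegression(max_iter=2000, random_state=seed, **params)
    elif family == "decision_tree":
        est = DecisionTreeClassifier(random_state=seed, **params)
    elif family == "random_forest":
        est = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    elif family == "gradient_boosting":
        est = GradientBoostingClassifier(random_state=seed, **params)
    elif family == "ada_boost":
        est = AdaBoostClassifier(random_state=seed, **params)
    elif family == "lightgbm":
        est = LGBMClassifier(
            random_state=seed, verbose=-1, n_jobs=1, min_child_samples=5, **params
        )
    elif family == "extra_trees":
        est = ExtraTreesClassifier(random_state=seed, n_jobs=1, **params)
    elif family == "feedforward":
        est = FeedForwardClassifier(random_state=seed, **params)
    else:
        raise ValueError(f"unknown model family {family!r}")
    if family in SCALED_FAMILIES:
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    return est


@dataclass
class TrainConfig:
    """Grid, cross-validation and resampling settings for one task."""

    families: tuple[str, ...] = tuple(DEFAULT_GRIDS)
    grids: dict[str, list[dict]] = field(
        default_factory=lambda: {k: [dict(p) for p in v] for k, v in DEFAULT_GRIDS.items()}
    )
    cv_folds: int = 10
    resampling: str = "none"
    test_size: float = 0.2
    seed: int = 0

    @classmethod
    def fast(cls, seed: int = 0, resampling: str = "none") -> "TrainConfig":
        """Reduced grid (logistic + shallow tree) for desk-scale runs."""
        return cls(
            families=("logistic", "decision_tree"),
            grids={
                "logistic": [{"C": 1.0}],
                "decision_tree": [{"max_depth": 5}],
            },
            cv_folds=5,
            resampling=resampling,
            seed=seed,
        )


class DegenerateDataError(ValueError):
    pass


@dataclass
class FitResult:
    """Selected model and metrics for one prediction task."""

    task: ModelTask | None
    family: str
    params: dict
    cv_results: pd.DataFrame
    cutoff: float
    train_metrics: dict
    test_metrics: dict
    marginal_effects: pd.Series
    model: object
    feature_names: list[str]

    def summary(self) -> dict:
        return {
            "task": self.task.key if self.task else None,
            "family": self.family,
            "params": self.params,
            "cutoff": self.cutoff,
            "train": {k: v for k, v in self.train_metrics.items()},
            "test": {k: v for k, v in self.test_metrics.items()},
            "marginal_effects_pp": self.marginal_effects.round(4).to_dict(),
        }


def _proba(model, X: np.ndarray) -> np.ndarray:
    return model.predict_proba(X)[:, 1]


def train_and_select(
    X: pd.DataFrame,
    y: pd.Series,
    config: TrainConfig,
    task: ModelTask | None = None,
) -> FitResult:
    """Grid search + stratified CV + F1 selection for one task.

    The data is first split into stratified train/test (``test_size``);
    resampling, cross-validation, model selection, refitting and cutoff
    optimization all happen on the training split. Deterministic for a
    fixed (data, config, seed).
    """
    y_arr = np.asarray(y, dtype=int)
    if len(np.unique(y_arr)) < 2:
        raise DegenerateDataError("training data contains a single class")
    X_arr = X.to_numpy(dtype=float)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X_arr, y_arr, test_size=config.test_size, stratify=y_arr,
        random_state=config.seed,
    )
    if len(np.unique(y_tr)) < 2:
        raise DegenerateDataError("training split contains a single class")
    n_folds = min(config.cv_folds, int(np.bincount(y_tr).min()))
    if n_folds < 2:
        raise DegenerateDataError("too few minority samples for cross-validation")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=config.seed)

    rows = []
    for family in config.families:
        for params in config.grids[family]:
            f1s, aucs, accs = [], [], []
            for fold_idx, (tr_idx, va_idx) in enumerate(cv.split(X_tr, y_tr)):
                X_fold, y_fold = X_tr[tr_idx], y_tr[tr_idx]
                if config.resampling != "none":
                    X_fold, y_fold = resample(
                        X_fold, y_fold, config.resampling,
                        seed=config.seed + fold_idx,
                        k_neighbors=min(5, int(np.bincount(y_fold).min()) - 1),
                    )
                est = make_estimator(family, params, config.seed)
                est.fit(X_fold, y_fold)
                fold_metrics = metrics(y_tr[va_idx], _proba(est, X_tr[va_idx]))
                f1s.append(fold_metrics["f1"])
                aucs.append(0.5 if fold_metrics["auc_undefined"] else fold_metrics["auc"])
                accs.append(fold_metrics["accuracy"])
            rows.append(
                {
                    "family": family,
                    "params": dict(params),
                    "cv_f1": float(np.mean(f1s)),
                    "cv_auc": float(np.mean(aucs)),
                    "cv_accuracy": float(np.mean(accs)),
                }
            )
    cv_results = pd.DataFrame(rows)
    best = cv_results.sort_values(
        ["cv_f1", "cv_auc", "cv_accuracy"], ascending=False, kind="stable"
    ).iloc[0]

    X_fit, y_fit = X_tr, y_tr
    if config.resampling != "none":
        X_fit, y_fit = resample(
            X_fit, y_fit, config.resampling, seed=config.seed,
            k_neighbors=min(5, int(np.bincount(y_fit).min()) - 1),
        )
    model = make_estimator(best["family"], best["params"], config.seed)
    model.fit(X_fit, y_fit)

    p_tr = _proba(model, X_tr)
    cutoff = kappa_optimal_cutoff(y_tr, p_tr)
    p_te = _proba(model, X_te)
    effects = marginal_effects(model, pd.DataFrame(X_te, columns=list(X.columns)))
    return FitResult(
        task=task,
        family=str(best["family"]),
        params=dict(best["params"]),
        cv_results=cv_results,
        cutoff=cutoff,
        train_metrics=metrics(y_tr, p_tr, cutoff),
        test_metrics=metrics(y_te, p_te, cutoff),
        marginal_effects=effects,
        model=model,
        feature_names=list(X.columns),
    )


def train_feedforward(
    X, y, grid: Sequence[Mapping] | None = None, seed: int = 0
) -> FeedForwardClassifier:
    """Grid search over the feed-forward network's regularization,
    learning rate and epochs; returns the best network by CV F1.

    Features must be standardized beforehand.
    """
    grid = grid or DEFAULT_GRIDS["feedforward"]
    config = TrainConfig(
        families=("feedforward",),
        grids={"feedforward": [dict(p) for p in grid]},
        cv_folds=3,
        seed=seed,
    )
    result = train_and_select(pd.DataFrame(np.asarray(X)), pd.Series(y), config)
    return result.model


def marginal_effects(model, X: pd.DataFrame) -> pd.Series:
    """Average change of the predicted probability per feature, in pp.

    Binary features (values ⊆ {0, 1}) are toggled 0→1; continuous
    features are shifted by +1 sample SD. The mean difference of the
    predicted probability over the sample is reported in percentage
    points.
    """
    base = X.to_numpy(dtype=float)
    effects = {}
    for j, col in enumerate(X.columns):
        values = np.unique(base[:, j])
        lo = base.copy()
        hi = base.copy()
        if set(values) <= {0.0, 1.0}:
            lo[:, j] = 0.0
            hi[:, j] = 1.0
        else:
            sd = float(np.std(base[:, j], ddof=1)) if len(base) > 1 else 0.0
            hi[:, j] = base[:, j] + sd
        effects[col] = 100.0 * float(np.mean(_proba(model, hi) - _proba(model, lo)))
    return pd.Series(effects, name="marginal_effect_pp")


# ---------------------------------------------------------------------------
# task bundle and the stage-probability calculator


class MissingFeatureError(KeyError):
    pass


def fit_all_tasks(
    staged: pd.DataFrame, config: TrainConfig
) -> dict[str, FitResult]:
    """Fit every task the staged panel supports; key = task key."""
    results: dict[str, FitResult] = {}
    for task in build_tasks():
        try:
            X, y = make_dataset(staged, task)
        except EmptyTaskError:
            continue
        if len(np.unique(y)) < 2:
            continue
        results[task.key] = train_and_select(X, y, config, task=task)
    return results


def predict_stage_probabilities(
    bundle: Mapping[str, FitResult],
    patient: Mapping[str, float],
    horizon: int,
    current_stage: Stage,
) -> pd.Series:
    """4-stage probability vector for one patient at a horizon.

    For a no-complication starter the goal-outcome and
    complication-outcome model probabilities are combined as an
    independent product over the two axes; for a complication starter
    all mass stays on the two YES stages.
    """
    goal_key = ModelTask(horizon, current_stage, OUTCOME_OUT_GOAL).key
    if goal_key not in bundle:
        raise KeyError(f"no fitted model for task {goal_key}")
    goal_fit = bundle[goal_key]
    missing = [f for f in goal_fit.feature_names if f not in patient]
    if missing:
        raise MissingFeatureError(f"missing required features: {missing}")
    row = np.array([[float(patient[f]) for f in goal_fit.feature_names]])
    p_out = float(_proba(goal_fit.model, row)[0])
    if current_stage.has_complication:
        vector = [0.0, 0.0, 1 - p_out, p_out]
    else:
        comp_key = ModelTask(horizon, current_stage, OUTCOME_COMPLICATION).key
        if comp_key not in bundle:
            raise KeyError(f"no fitted model for task {comp_key}")
        comp_fit = bundle[comp_key]
        row_c = np.array([[float(patient[f]) for f in comp_fit.feature_names]])
        p_comp = float(_proba(comp_fit.model, row_c)[0])
        vector = [
            (1 - p_out) * (1 - p_comp),
            p_out * (1 - p_comp),
            (1 - p_out) * p_comp,
            p_out * p_comp,
        ]
    return pd.Series(vector, index=[s.value for s in STAGE_ORDER], name="probability")
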