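"""Two-stage random-forest classification with patient-level splits.

Stage one grows a forest F on the training tiles using all 56 features and
ranks features by Gini importance (mean impurity decrease, normalized to
sum 1).  Stage two keeps the top-N features, grows a second forest F' on the
reduced data and classifies the held-out test tiles.  Splits are made at the
patient level — every tile of a patient lands in exactly one of the train /
validation / test sets — so tiles from one capsule can never leak across
sets.  Library baselines (KNN, linear and RBF SVM, AdaBoost) run on the same
splits with all features for comparison.

Defaults: T = 450 trees, N = 30 features, m = ceil(sqrt(p)) features tried
per node, 10 repeated splits at roughly 60/20/20 patients per class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .selection import FeatureTable

__all__ = [
    "SplitPlan",
    "ForestModel",
    "ImportanceRanking",
    "MetricsReport",
    "make_patient_splits",
    "permute_patient_labels",
    "fit_forest",
    "gini_impurity",
    "gini_importances",
    "select_top_n",
    "run_two_stage",
    "evaluate",
    "run_repeated",
    "run_baselines",
    "macro_f1",
]

DEFAULT_TREES = 450
DEFAULT_TOP_N = 30
DEFAULT_FRACTIONS = (0.6, 0.2, 0.2)


@dataclass(frozen=True)
class SplitPlan:
    """A patient-level partition into train / validation / test."""

    train: frozenset
    validation: frozenset
    test: frozenset
    repeat_index: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        sets = (self.train, self.validation, self.test)
        for a in range(3):
            for b in range(a + 1, 3):
                if sets[a] & sets[b]:
                    raise ValueError("split sets must be pairwise disjoint")

    def set_of(self, patient_id: str) -> str:
        if patient_id in self.train:
            return "train"
        if patient_id in self.validation:
            return "validation"
        if patient_id in self.test:
            return "test"
        raise KeyError(patient_id)


def make_patient_splits(
    table: FeatureTable,
    repeats: int = 10,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> list[SplitPlan]:
    """Repeated stratified-by-class random partitions of patient IDs.

    Each class contributes at least one patient to every set, which requires
    >= 3 patients per class.  Deterministic from ``seed``.
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError("fractions must sum to 1")
    pid_label: dict[str, str] = {}
    for label, pid in zip(table.labels, table.patient_ids):
        if pid_label.setdefault(pid, label) != label:
            raise ValueError(
                f"patient {pid!r} carries multiple class labels; patient-level "
                "stratification is undefined"
            )
    by_class: dict[str, list[str]] = {}
    for pid, label in pid_label.items():
        by_class.setdefault(label, []).append(pid)
    for label, pids in by_class.items():
        if len(pids) < 3:
            raise ValueError(
                f"class {label!r} has {len(pids)} patient(s); need >= 3 to fill "
                "train/validation/test"
            )
    rng = np.random.default_rng(seed)
    plans = []
    for rep in range(repeats):
        train: set[str] = set()
        val: set[str] = set()
        test: set[str] = set()
        for label in sorted(by_class):
            pids = sorted(by_class[label])
            order = rng.permutation(len(pids))
            n = len(pids)
            n_val = max(1, round(fractions[1] * n))
            n_test = max(1, round(fractions[2] * n))
            if n_val + n_test >= n:  # keep >= 1 patient in train
                n_val = n_test = 1
            shuffled = [pids[i] for i in order]
            val.update(shuffled[:n_val])
            test.update(shuffled[n_val : n_val + n_test])
            train.update(shuffled[n_val + n_test :])
        plans.append(SplitPlan(frozenset(train), frozenset(val), frozenset(test), rep, seed))
    return plans


def permute_patient_labels(table: FeatureTable, seed: int = 0) -> FeatureTable:
    """Null cohort: shuffle class labels across patients (tiles follow).

    Permuting at the patient level keeps every patient single-labeled, so
    patient-level splits remain well defined while any real class signal is
    destroyed.
    """
    pids = sorted(set(table.patient_ids))
    pid_label = {p: l for p, l in zip(table.patient_ids, table.labels)}
    labels = [pid_label[p] for p in pids]
    rng = np.random.default_rng(seed)
    shuffled = [labels[i] for i in rng.permutation(len(labels))]
    new_map = dict(zip(pids, shuffled))
    return FeatureTable(
        table.X,
        table.feature_names,
        np.array([new_map[p] for p in table.patient_ids], dtype=object),
        table.patient_ids,
    )


@dataclass(eq=False)
class ForestModel:
    """A fitted random forest plus the hyperparameters that grew it."""

    estimator: RandomForestClassifier
    n_trees: int
    m_features: int
    seed: int
    feature_names: tuple[str, ...] = ()

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(X)


def gini_impurity(class_counts) -> float:
    """Gini impurity 1 - sum((n_c / n)^2) of a node's class counts."""
    counts = np.asarray(class_counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("node must contain at least one sample")
    frac = counts / n
    return float(1.0 - (frac * frac).sum())


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = DEFAULT_TREES,
    m_features: int | None = None,
    seed: int = 0,
    feature_names: tuple[str, ...] = (),
    oob_score: bool = False,
) -> ForestModel:
    """Grow a Gini random forest on bootstrap samples.

    ``m_features`` (features tried per node) defaults to ceil(sqrt(p)).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(set(y)) < 2:
        raise ValueError("training data must contain at least two classes")
    m = m_features or math.ceil(math.sqrt(X.shape[1]))
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features=m,
        bootstrap=True,
        min_samples_leaf=1,
        random_state=seed,
        oob_score=oob_score,
        n_jobs=1,
    )
    clf.fit(X, y)
    return ForestModel(clf, n_trees, m, seed, tuple(feature_names))


@dataclass(eq=False)
class ImportanceRanking:
    """Normalized Gini importances with a deterministic rank order."""

    importances: np.ndarray
    order: np.ndarray  # feature indices, most important first
    feature_names: tuple[str, ...] = ()

    def top_n_mask(self, n: int) -> np.ndarray:
        mask = np.zeros(len(self.importances), dtype=bool)
        mask[select_top_n(self, n)] = True
        return mask


def gini_importances(model: ForestModel) -> ImportanceRanking:
    """Mean impurity-decrease importances, normalized to sum to 1.

    Ties in the ranking break toward the lower feature index.
    """
    imp = np.asarray(model.estimator.feature_importances_, dtype=float)
    total = imp.sum()
    if total <= 0:
        warnings.warn("forest made no impurity-reducing splits; importances all 0")
    else:
        imp = imp / total
    order = np.argsort(-imp, kind="stable")
    return ImportanceRanking(imp, order, model.feature_names)


def select_top_n(ranking: ImportanceRanking, n: int) -> np.ndarray:
    """Indices of the N most important features (ties -> lower index)."""
    if n < 1:
        raise ValueError("N must be >= 1")
    return ranking.order[: min(n, len(ranking.importances))]


def evaluate(y_true, y_pred, classes=None) -> pd.DataFrame:
    """One-vs-rest precision, recall and F1 per class (0/0 := 0)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    classes = list(classes) if classes is not None else sorted(set(y_true) | set(y_pred))
    rows = []
    for c in classes:
        tp = int(((y_true == c) & (y_pred == c)).sum())
        fp = int(((y_true != c) & (y_pred == c)).sum())
        fn = int(((y_true == c) & (y_pred != c)).sum())
        if tp + fp + fn == 0:
            warnings.warn(f"class {c!r} absent from truth and prediction; metrics 0")
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        rows.append({"class": c, "precision": precision, "recall": recall, "f1": f1})
    return pd.DataFrame(rows).set_index("class")


def macro_f1(metrics: pd.DataFrame) -> float:
    return float(metrics["f1"].mean())


def _subset(table: FeatureTable, patients: frozenset) -> tuple[np.ndarray, np.ndarray]:
    rows = np.isin(table.patient_ids.astype(str), sorted(str(p) for p in patients))
    return table.X[rows], table.labels[rows]


@dataclass(eq=False)
class TwoStageResult:
    ranking: ImportanceRanking
    selected: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    metrics: pd.DataFrame


def run_two_stage(
    table: FeatureTable,
    plan: SplitPlan,
    n_trees: int = DEFAULT_TREES,
    top_n: int = DEFAULT_TOP_N,
    seed: int = 0,
) -> TwoStageResult:
    """Forest F on all features -> Gini top-N -> forest F' -> test metrics.

    The table is first put into canonical (name-sorted) column order and the
    selected index set is applied in ascending order, so predictions do not
    depend on the caller's column order and top_n = p is a strict no-op.
    """
    _assert_no_leakage(plan)
    table = table.sorted_by_feature_name()
    X_train, y_train = _subset(table, plan.train)
    X_test, y_test = _subset(table, plan.test)
    forest_f = fit_forest(
        X_train, y_train, n_trees=n_trees, seed=seed, feature_names=table.feature_names
    )
    ranking = gini_importances(forest_f)
    selected = np.sort(select_top_n(ranking, top_n))
    forest_fp = fit_forest(
        X_train[:, selected],
        y_train,
        n_trees=n_trees,
        seed=seed + 1,
        feature_names=tuple(table.feature_names[i] for i in selected),
    )
    y_pred = forest_fp.predict(X_test[:, selected])
    classes = sorted(set(table.labels))
    return TwoStageResult(ranking, selected, y_test, y_pred, evaluate(y_test, y_pred, classes))


def _assert_no_leakage(plan: SplitPlan) -> None:
    sets = (plan.train, plan.validation, plan.test)
    for a in range(3):
        for b in range(a + 1, 3):
            leaked = sets[a] & sets[b]
            if leaked:
                raise AssertionError(f"patient leakage across splits: {sorted(leaked)}")


@dataclass(eq=False)
class MetricsReport:
    """Per-class precision/recall/F1, mean +/- SD over repeated splits."""

    per_repeat: list[pd.DataFrame]
    confusions: list[np.ndarray]
    classes: tuple[str, ...]

    def summary(self) -> pd.DataFrame:
        stacked = pd.concat(self.per_repeat, keys=range(len(self.per_repeat)))
        mean = stacked.groupby(level=1).mean()
        sd = stacked.groupby(level=1).std(ddof=1).fillna(0.0)
        out = mean.join(sd, lsuffix="_mean", rsuffix="_sd")
        return out.loc[list(self.classes)]

    def to_dict(self) -> dict:
        s = self.summary()
        return {
            c: {
                m: {"mean": float(s.loc[c, f"{m}_mean"]), "sd": float(s.loc[c, f"{m}_sd"])}
                for m in ("precision", "recall", "f1")
            }
            for c in self.classes
        }


def run_repeated(
    table: FeatureTable,
    plans: list[SplitPlan],
    n_trees: int = DEFAULT_TREES,
    top_n: int = DEFAULT_TOP_N,
    seed: int = 0,
) -> MetricsReport:
    """The two-stage procedure over repeated splits, aggregated."""
    classes = tuple(sorted(set(table.labels)))
    per_repeat, confusions = [], []
    for i, plan in enumerate(plans):
        res = run_two_stage(table, plan, n_trees=n_trees, top_n=top_n, seed=seed + 1000 * i)
        per_repeat.append(res.metrics)
        confusions.append(confusion_matrix(res.y_true, res.y_pred, labels=list(classes)))
    return MetricsReport(per_repeat, confusions, classes)


def _baseline_estimators(seed: int) -> dict[str, object]:
    return {
        "KNN": KNeighborsClassifier(n_neighbors=5),
        "SVM_linear": SVC(kernel="linear", random_state=seed),
        "SVM_RBF": SVC(kernel="rbf", random_state=seed),
        "AdaBoost": AdaBoostClassifier(n_estimators=100, random_state=seed),
    }


def run_baselines(
    table: FeatureTable, plans: list[SplitPlan], seed: int = 0
) -> dict[str, MetricsReport]:
    """Library baselines on all features, standardized per training split."""
    table = table.sorted_by_feature_name()
    classes = tuple(sorted(set(table.labels)))
    reports: dict[str, MetricsReport] = {}
    for name, est in _baseline_estimators(seed).items():
        per_repeat, confusions = [], []
        for plan in plans:
            _assert_no_leakage(plan)
            X_train, y_train = _subset(table, plan.train)
            X_test, y_test = _subset(table, plan.test)
            pipe = make_pipeline(StandardScaler(), est)
            pipe.fit(X_train, y_train)
            y_pred = pipe.predict(X_test)
            per_repeat.append(evaluate(y_test, y_pred, classes))
            confusions.append(confusion_matrix(y_test, y_pred, labels=list(classes)))
        reports[name] = MetricsReport(per_repeat, confusions, classes)
    return reports
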