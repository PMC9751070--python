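"""Per-feature statistics: Fisher scores and one-way ANOVA with Holm control.

The Fisher score of feature j over classes k with per-class sizes n_k,
means mu_kj and population variances s2_kj is

    F_j = sum_k n_k (mu_kj - mu_j)^2  /  sum_k n_k s2_kj

the ratio of between-class to within-class variability.  Features scoring
above the mean score over all features are retained — a simple supervised
filter.  One-way ANOVA with step-down Holm adjustment provides the
per-feature significance assessment at alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .types import STRATEGIES

__all__ = [
    "FeatureTable",
    "FisherResult",
    "fisher_scores",
    "anova_oneway",
    "anova_table",
    "holm_adjust",
    "significance_stars",
    "fisher_grid",
]


@dataclass(eq=False)
class FeatureTable:
    """Feature matrix with per-row class labels and patient identifiers."""

    X: np.ndarray
    feature_names: tuple[str, ...]
    labels: np.ndarray
    patient_ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match the number of columns")
        if len(self.labels) != self.X.shape[0] or len(self.patient_ids) != self.X.shape[0]:
            raise ValueError("labels/patient_ids must match the number of rows")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains missing/non-finite values")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        """Build from an extract_table-style frame (tile_id, label,
        patient_id, size, features...)."""
        meta = [c for c in ("tile_id", "label", "patient_id", "size") if c in df.columns]
        feats = [c for c in df.columns if c not in meta]
        return cls(
            df[feats].to_numpy(float),
            tuple(feats),
            df["label"].to_numpy(),
            df["patient_id"].to_numpy(),
        )

    def sorted_by_feature_name(self) -> "FeatureTable":
        """Columns reordered to sorted feature names (a canonical layout,
        so fitted models do not depend on the caller's column order)."""
        order = np.argsort(np.array(self.feature_names, dtype=object))
        return FeatureTable(
            self.X[:, order],
            tuple(self.feature_names[i] for i in order),
            self.labels,
            self.patient_ids,
        )

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


@dataclass(eq=False)
class FisherResult:
    scores: np.ndarray
    mean_score: float
    selected: np.ndarray  # score strictly above the mean score
    feature_names: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": list(self.feature_names),
                "fisher_score": self.scores,
                "selected": self.selected,
            }
        )


def fisher_scores(table: FeatureTable) -> FisherResult:
    """Fisher score per feature with mean-score selection threshold.

    Uses population (biased) class variances.  A feature whose pooled
    within-class variance is zero gets score 0 with a warning.
    """
    classes = table.classes
    if len(classes) < 2:
        raise ValueError("Fisher scoring needs at least two classes")
    groups = {c: table.X[table.labels == c] for c in classes}
    for c, g in groups.items():
        if g.shape[0] < 2:
            raise ValueError(f"class {c!r} needs at least two rows")
    overall = table.X.mean(axis=0)
    num = np.zeros(table.X.shape[1])
    den = np.zeros(table.X.shape[1])
    for g in groups.values():
        n_k = g.shape[0]
        num += n_k * (g.mean(axis=0) - overall) ** 2
        den += n_k * g.var(axis=0)  # population variance
    scores = np.zeros_like(num)
    zero = den <= 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} feature(s) with zero within-class variance scored 0"
        )
    np.divide(num, den, out=scores, where=~zero)
    mean_score = float(scores.mean())
    return FisherResult(scores, mean_score, scores > mean_score, table.feature_names)


def anova_oneway(groups) -> tuple[float, float]:
    """Classic one-way ANOVA F statistic and p value.

    ``groups`` is an iterable of per-class value sequences.  When both the
    between- and within-group sums of squares vanish (all values equal)
    F := 0 with p = 1.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    n = sum(g.size for g in gs)
    k = len(gs)
    grand = np.concatenate(gs).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    if ssw <= 0:
        if ssb <= 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ssb / (k - 1)) / (ssw / (n - k))
    p = float(scipy.stats.f.sf(f, k - 1, n - k))
    return float(f), p


def holm_adjust(p, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down adjusted p values and rejection flags at ``alpha``."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p, np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return p_adj, reject


def significance_stars(p_adj: float) -> str:
    """GraphPad-style star codes on adjusted p values."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p_adj <= cut:
            return stars
    return "ns"


def anova_table(table: FeatureTable, alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature one-way ANOVA across classes with Holm adjustment."""
    classes = table.classes
    if len(classes) < 2:
        raise ValueError("ANOVA needs at least two classes")
    stats = [
        anova_oneway([table.X[table.labels == c, j] for c in classes])
        for j in range(table.X.shape[1])
    ]
    f_vals = np.array([s[0] for s in stats])
    p_vals = np.array([s[1] for s in stats])
    p_adj, reject = holm_adjust(p_vals, alpha)
    return pd.DataFrame(
        {
            "feature": list(table.feature_names),
            "F": f_vals,
            "p": p_vals,
            "p_holm": p_adj,
            "significant": reject,
            "stars": [significance_stars(q) for q in p_adj],
        }
    )


def fisher_grid(result: FisherResult) -> pd.DataFrame:
    """Pivot a 56-feature Fisher result into a feature x strategy grid.

    Rows are the 14 per-strategy feature names; columns are the four
    conversion strategies; a trailing column set flags selection.
    """
    rows: dict[str, dict[str, float]] = {}
    flags: dict[str, dict[str, bool]] = {}
    for name, score, sel in zip(result.feature_names, result.scores, result.selected):
        strategy, short = name.split(".", 1)
        rows.setdefault(short, {})[strategy] = score
        flags.setdefault(short, {})[f"{strategy}_selected"] = bool(sel)
    grid = pd.DataFrame(rows).T
    flag_df = pd.DataFrame(flags).T
    grid = grid.join(flag_df)
    order = [s for s in STRATEGIES if s in grid.columns]
    order += [c for c in grid.columns if c not in order]
    return grid[order]
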