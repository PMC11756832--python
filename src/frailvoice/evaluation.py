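"""Cross-validated evaluation protocol: balanced folds, metrics, CIs, tests.

The protocol mirrors the frailty-screening study this package models: 5-fold
cross-validation with class-stratified ("balanced") folds; per-fold accuracy,
ROC AUC, sensitivity and specificity summarized as mean with a normal 95% CI
(mean +/- 1.96 * SD / sqrt(k), the convention the study's reported tables
follow); paired fold-level t-tests (df = k-1) for model comparisons; a
prevalence-shifted sensitivity analysis at 20% positive prevalence; and
classical baselines (logistic regression, decision tree, random forest) on
per-clip functional features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "FoldSplit",
    "MetricSet",
    "SummaryStats",
    "CVResult",
    "TestResult",
    "make_balanced_folds",
    "compute_roc_auc",
    "compute_metrics",
    "summarize_folds",
    "paired_auc_ttest",
    "evaluate_imbalanced",
    "train_baseline",
    "roc_points",
    "plot_roc_curves",
    "METRIC_NAMES",
]

METRIC_NAMES = ("accuracy", "auc", "sensitivity", "specificity")


@dataclass(frozen=True)
class FoldSplit:
    """Stratified k-fold partition: ``assignments[i]`` is sample i's fold."""

    k: int
    assignments: np.ndarray

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)

    def per_fold_label_counts(self, labels: np.ndarray) -> list[dict[int, int]]:
        out = []
        for f in range(self.k):
            idx = self.fold_indices(f)
            vals, counts = np.unique(labels[idx], return_counts=True)
            out.append({int(v): int(c) for v, c in zip(vals, counts)})
        return out


@dataclass(frozen=True)
class MetricSet:
    """Threshold metrics plus AUC for one validation fold (accuracy in %)."""

    accuracy: float
    auc: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    min: float
    max: float

    def rounded(self, ndigits: int = 2) -> "SummaryStats":
        return SummaryStats(*(round(v, ndigits) for v in
                              (self.mean, self.sd, self.ci_low, self.ci_high,
                               self.min, self.max)))


@dataclass(frozen=True)
class TestResult:
    """Paired fold-level t-test between two models' per-fold AUCs."""

    t: float
    df: int
    p: float
    mean_difference: float
    differences: tuple[float, ...]
    degenerate: bool = False


@dataclass
class CVResult:
    """Per-fold metric sets with per-metric summaries."""

    model: str
    per_fold: list[MetricSet]
    summaries: dict[str, SummaryStats]

    @property
    def k(self) -> int:
        return len(self.per_fold)

    def fold_values(self, metric: str) -> np.ndarray:
        return np.array([getattr(m, metric) for m in self.per_fold])

    def summary(self) -> str:
        """Text table in the study's reporting layout: mean (95% CI), min, max."""
        lines = [f"{self.model}: {self.k}-fold cross-validation"]
        header = f"  {'metric':<12}{'mean (95% CI)':>26}{'min':>9}{'max':>9}"
        lines.append(header)
        for m in METRIC_NAMES:
            s = self.summaries[m].rounded()
            lines.append(
                f"  {m:<12}{s.mean:>10.2f} ({s.ci_low:.2f}-{s.ci_high:.2f})"
                f"{'':>4}{s.min:>9.2f}{s.max:>9.2f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "per_fold": [asdict(m) for m in self.per_fold],
            "summaries": {m: asdict(s) for m, s in self.summaries.items()},
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def per_fold_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(m) for m in self.per_fold]).assign(model=self.model)


def make_balanced_folds(labels: np.ndarray, k: int = 5, seed: int = 0) -> FoldSplit:
    """Stratified fold assignment: shuffle within class, deal round-robin.

    Guarantees fold sizes within +/-1 and per-fold class counts within +/-1 of
    the stratified ideal.  Requires each class to have at least k members.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    assignments = np.full(len(labels), -1, dtype=int)
    load = np.zeros(k, dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < k:
            raise ValueError(f"class {c} has {len(idx)} members, fewer than k={k}")
        idx = rng.permutation(idx)
        base, rem = divmod(len(idx), k)
        # class counts of base or base+1 per fold; the +1s go to the folds
        # currently lightest so total fold sizes also stay within one
        order = np.lexsort((np.arange(k), load))
        counts = np.full(k, base)
        counts[order[:rem]] += 1
        pos = 0
        for f in range(k):
            assignments[idx[pos : pos + counts[f]]] = f
            pos += counts[f]
        load += counts
    return FoldSplit(k=k, assignments=assignments)


def compute_roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC = all-pairs concordance probability with ties counting 0.5."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes in the labels")
    return float(roc_auc_score(labels, np.asarray(scores)))


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricSet:
    """Confusion-matrix metrics at a threshold (positive iff score >= threshold)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("metrics require both classes in the labels")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    return MetricSet(
        accuracy=100.0 * (tp + tn) / len(labels),
        auc=compute_roc_auc(scores, labels),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def summarize_folds(per_fold_values: np.ndarray, k: int | None = None) -> SummaryStats:
    """Mean, sample SD and normal 95% CI (mean +/- 1.96*SD/sqrt(k)) over folds."""
    v = np.asarray(per_fold_values, dtype=float)
    if k is None:
        k = len(v)
    if k < 2 or len(v) != k:
        raise ValueError("summarize_folds needs k >= 2 values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    half = 1.96 * sd / np.sqrt(k)
    return SummaryStats(mean, sd, mean - half, mean + half, float(v.min()), float(v.max()))


def summarize_metrics(model: str, per_fold: list[MetricSet]) -> CVResult:
    summaries = {
        m: summarize_folds(np.array([getattr(f, m) for f in per_fold]))
        for m in METRIC_NAMES
    }
    return CVResult(model=model, per_fold=per_fold, summaries=summaries)


def paired_auc_ttest(aucs_a: np.ndarray, aucs_b: np.ndarray) -> TestResult:
    """Paired t-test on per-fold AUC differences, df = k - 1, two-sided p."""
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("per-fold AUC vectors must have equal length")
    if len(a) < 2:
        raise ValueError("need at least two folds")
    d = a - b
    k = len(d)
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d == 0.0:
        if mean_d == 0.0:
            return TestResult(0.0, k - 1, 1.0, 0.0, tuple(d))
        return TestResult(
            float(np.sign(mean_d) * np.inf), k - 1, 0.0, mean_d, tuple(d), degenerate=True
        )
    t = mean_d / (sd_d / np.sqrt(k))
    p = float(2.0 * stats.t.sf(abs(t), df=k - 1))
    return TestResult(float(t), k - 1, p, mean_d, tuple(d))


def evaluate_imbalanced(
    scores: np.ndarray,
    labels: np.ndarray,
    target_prevalence: float = 0.20,
    repeats: int = 20,
    seed: int = 0,
    threshold: float = 0.5,
) -> dict:
    """Metrics on prevalence-shifted validation sets built by subsampling positives.

    All negatives are kept; positives are subsampled (without replacement) to
    the largest count whose prevalence does not exceed the target.  Metrics are
    averaged over ``repeats`` seeded resamples.  Returns the averaged metrics,
    the achieved prevalence, and whether the target was attainable exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    neg = np.flatnonzero(labels == 0)
    pos = np.flatnonzero(labels == 1)
    n_neg = len(neg)
    if n_neg == 0 or len(pos) == 0:
        raise ValueError("pool must contain both classes")
    n_pos = int(np.floor(n_neg * target_prevalence / (1.0 - target_prevalence)))
    if n_pos < 1:
        raise ValueError("target prevalence unattainable: too few negatives in pool")
    if n_pos > len(pos):
        raise ValueError(
            f"target prevalence needs {n_pos} positives but pool has {len(pos)}"
        )
    achieved = n_pos / (n_pos + n_neg)
    rng = np.random.default_rng(seed)
    metric_rows = []
    for _ in range(repeats):
        take = rng.choice(pos, size=n_pos, replace=False)
        idx = np.concatenate([neg, take])
        m = compute_metrics(scores[idx], labels[idx], threshold)
        metric_rows.append(m.as_dict())
    averaged = {k: float(np.mean([r[k] for r in metric_rows])) for k in METRIC_NAMES}
    return {
        "metrics": averaged,
        "per_repeat": metric_rows,
        "n_negative": n_neg,
        "n_positive": n_pos,
        "achieved_prevalence": achieved,
        "exact": abs(achieved - target_prevalence) < 1e-12,
        "target_prevalence": target_prevalence,
    }


_BASELINES = {
    "logistic_regression": lambda seed: make_pipeline(
        StandardScaler(), LogisticRegression(C=1.0, max_iter=2000, random_state=seed)
    ),
    "decision_tree": lambda seed: DecisionTreeClassifier(max_depth=5, random_state=seed),
    "random_forest": lambda seed: RandomForestClassifier(
        n_estimators=100, random_state=seed
    ),
}


def train_baseline(
    kind: str,
    functionals: np.ndarray,
    labels: np.ndarray,
    folds: FoldSplit,
    seed: int = 0,
) -> CVResult:
    """Cross-validate a classical model on per-clip functional features."""
    if kind not in _BASELINES:
        raise ValueError(f"kind must be one of {sorted(_BASELINES)}")
    x = np.asarray(functionals, dtype=float)
    y = np.asarray(labels).astype(int)
    per_fold = []
    for f in range(folds.k):
        tr, va = folds.train_indices(f), folds.fold_indices(f)
        model = _BASELINES[kind](seed)
        model.fit(x[tr], y[tr])
        p = model.predict_proba(x[va])[:, 1]
        per_fold.append(compute_metrics(p, y[va]))
    return summarize_metrics(kind, per_fold)


def roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    fpr, tpr, thr = roc_curve(np.asarray(labels).astype(int), np.asarray(scores))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def plot_roc_curves(
    fold_scores: list[np.ndarray],
    fold_labels: list[np.ndarray],
    title: str,
    path: str | Path,
) -> Path:
    """Per-fold ROC curves (one figure) written to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for i, (s, y) in enumerate(zip(fold_scores, fold_labels)):
        pts = roc_points(s, y)
        ax.plot(pts.fpr, pts.tpr, label=f"fold {i + 1} (AUC {compute_roc_auc(s, y):.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
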