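"""Classifier evaluation: confusion-matrix metrics, multiclass MCC, Cohen's
kappa, RMSE, cross-validation harnesses, and one-way ANOVA with Tukey HSD.

Per-class rates use one-vs-rest reductions of the confusion matrix and are
macro-averaged.  The multiclass Matthews correlation coefficient is computed
from the matrix totals

    MCC = (c*s - sum_k p_k t_k)
          / sqrt((s^2 - sum_k p_k^2) * (s^2 - sum_k t_k^2))

where c is the diagonal total, s the grand total, p_k the column (predicted)
totals and t_k the row (true) totals.  Cohen's kappa is
(P_o - P_e) / (1 - P_e) with P_o = c/s and P_e = sum_k (t_k/s)(p_k/s).

The cross-validation harnesses take ``train_fn(train_ds) -> fitted`` and
``eval_fn(fitted, test_ds) -> MetricReport`` callables, so any data-dependent
step (oversampling, feature scaling, model fitting) runs strictly inside the
training partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class ConfusionMatrix:
    """K x K counts; rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K classes")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def totals(self):
        """(c, s, p_k, t_k): diagonal sum, grand total, column and row totals."""
        c = float(np.trace(self.counts))
        s = float(self.counts.sum())
        p = self.counts.sum(axis=0).astype(float)  # predicted-class totals
        t = self.counts.sum(axis=1).astype(float)  # true-class totals
        return c, s, p, t

    def one_vs_rest(self, k: int):
        """(TP, FP, FN, TN) for class index k."""
        tp = float(self.counts[k, k])
        fp = float(self.counts[:, k].sum() - tp)
        fn = float(self.counts[k, :].sum() - tp)
        tn = float(self.counts.sum() - tp - fp - fn)
        return tp, fp, fn, tn


@dataclass
class MetricReport:
    """Macro and per-class rates plus MCC, kappa and (optionally) RMSE."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    mcc: float
    kappa: float
    overall_accuracy: float = 0.0  # plain fraction correct (trace / total)
    rmse: float | None = None
    per_class: dict = field(default_factory=dict)
    degenerate: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "overall_accuracy": self.overall_accuracy,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "specificity": self.specificity,
            "mcc": self.mcc,
            "kappa": self.kappa,
        }
        if self.rmse is not None:
            out["rmse"] = self.rmse
        return out


def confusion_matrix(y_true, y_pred, classes) -> ConfusionMatrix:
    """Count matrix with counts[i, j] = #(true == classes[i], pred == classes[j])."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label outside class set: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, list(classes))


def _safe_div(num: float, den: float, flags: list, name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def basic_metrics(cm: ConfusionMatrix) -> MetricReport:
    """One-vs-rest accuracy/precision/recall/F1/specificity, macro-averaged."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    per_class: dict = {}
    flags: list = []
    for k, name in enumerate(cm.classes):
        tp, fp, fn, tn = cm.one_vs_rest(k)
        acc = (tp + tn) / (tp + tn + fn + fp)
        pre = _safe_div(tp, tp + fp, flags, f"precision[{name}]")
        rec = _safe_div(tp, tp + fn, flags, f"recall[{name}]")
        f1 = _safe_div(2 * pre * rec, pre + rec, flags, f"f1[{name}]")
        spe = _safe_div(tn, tn + fp, flags, f"specificity[{name}]")
        per_class[name] = {
            "accuracy": acc, "precision": pre, "recall": rec,
            "f1": f1, "specificity": spe,
        }
    macro = {
        m: float(np.mean([per_class[c][m] for c in cm.classes]))
        for m in ("accuracy", "precision", "recall", "f1", "specificity")
    }
    return MetricReport(
        accuracy=macro["accuracy"],
        precision=macro["precision"],
        recall=macro["recall"],
        f1=macro["f1"],
        specificity=macro["specificity"],
        mcc=mcc(cm),
        kappa=kappa(cm),
        overall_accuracy=float(np.trace(cm.counts)) / cm.n,
        per_class=per_class,
        degenerate=flags,
    )


def mcc(cm: ConfusionMatrix) -> float:
    """Multiclass Matthews correlation coefficient; 0 when degenerate."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    c, s, p, t = cm.totals()
    num = c * s - float(p @ t)
    den = math.sqrt((s * s - float(p @ p)) * (s * s - float(t @ t)))
    if den == 0:
        return 0.0
    return num / den


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa (P_o - P_e) / (1 - P_e); degenerate P_e == 1 handled."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    c, s, p, t = cm.totals()
    p_o = c / s
    p_e = float((t / s) @ (p / s))
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def rmse(onehot: np.ndarray, probs: np.ndarray) -> float:
    """Root mean squared error over all n*K entries of truth vs probability."""
    onehot, probs = np.asarray(onehot, float), np.asarray(probs, float)
    if onehot.shape != probs.shape:
        raise ValueError("shape mismatch between truth and predictions")
    return float(np.sqrt(np.mean((onehot - probs) ** 2)))


def stratified_folds(labels, k: int, seed: int) -> list[np.ndarray]:
    """Index arrays of k stratified folds with balanced total sizes.

    Within each class the fold sizes differ by at most one; each class's
    remainder is assigned round-robin starting where the previous class's
    extras stopped, so the total fold sizes also stay within one of each
    other (972 samples, k=5 -> sizes 195/195/194/194/194).
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    extra_offset = 0
    for cls in sorted(set(labels.tolist())):
        idx = np.nonzero(labels == cls)[0]
        if idx.size < k:
            raise ValueError(f"class {cls!r} has {idx.size} < k={k} members")
        idx = rng.permutation(idx)
        base, rem = divmod(idx.size, k)
        sizes = np.full(k, base)
        for j in range(rem):
            sizes[(extra_offset + j) % k] += 1
        extra_offset = (extra_offset + rem) % k
        start = 0
        for f in range(k):
            folds[f].extend(idx[start : start + sizes[f]].tolist())
            start += sizes[f]
    return [np.sort(np.asarray(f)) for f in folds]


def kfold_cv(dataset, labels, k: int, seed: int, train_fn, eval_fn):
    """Stratified k-fold cross-validation.

    ``dataset`` is indexable by an integer index array (e.g. a numpy array of
    images); every sample is tested exactly once.  Returns the per-fold
    reports plus mean/SD of each scalar metric.
    """
    labels = np.asarray(labels)
    folds = stratified_folds(labels, k, seed)
    all_idx = np.arange(len(labels))
    reports = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        fitted = train_fn((dataset[train_idx], labels[train_idx]))
        reports.append(eval_fn(fitted, (dataset[test_idx], labels[test_idx])))
    scalars = {}
    for name in (
        "overall_accuracy", "accuracy", "precision", "recall", "f1",
        "specificity", "mcc", "kappa",
    ):
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        scalars[name] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}
    return reports, scalars


def stratified_split(labels, test_fraction: float, seed: int):
    """(train_idx, test_idx) for a stratified hold-out split."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    test: list[int] = []
    for cls in sorted(set(labels.tolist())):
        idx = rng.permutation(np.nonzero(labels == cls)[0])
        n_test = int(round(idx.size * test_fraction))
        if n_test == 0 or n_test == idx.size:
            raise ValueError(f"split leaves class {cls!r} empty on one side")
        test.extend(idx[:n_test].tolist())
    test_idx = np.sort(np.asarray(test))
    train_idx = np.setdiff1d(np.arange(len(labels)), test_idx)
    return train_idx, test_idx


def holdout_cv(dataset, labels, test_fraction: float, seed: int, train_fn, eval_fn):
    """Single stratified hold-out evaluation (same no-leakage contract)."""
    labels = np.asarray(labels)
    train_idx, test_idx = stratified_split(labels, test_fraction, seed)
    fitted = train_fn((dataset[train_idx], labels[train_idx]))
    return eval_fn(fitted, (dataset[test_idx], labels[test_idx]))


@dataclass
class AnovaResult:
    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    f_stat: float
    p_value: float
    group_means: list = field(default_factory=list)
    flags: list = field(default_factory=list)


def one_way_anova(groups: list) -> AnovaResult:
    """Fixed-effects one-way ANOVA from group sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    means = [float(g.mean()) for g in groups]
    ss_between = float(sum(g.size * (m - grand) ** 2 for g, m in zip(groups, means)))
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    df_between = len(groups) - 1
    df_within = all_vals.size - len(groups)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    flags: list = []
    if ms_within == 0:
        flags.append("zero within-group variance")
        f_stat = 0.0 if ss_between == 0 else math.inf
        p_value = 1.0 if ss_between == 0 else 0.0
    else:
        f_stat = ms_between / ms_within
        p_value = float(stats.f.sf(f_stat, df_between, df_within))
    return AnovaResult(
        ss_between, ss_within, ss_between + ss_within,
        df_between, df_within, ms_between, ms_within,
        f_stat, p_value, means, flags,
    )


@dataclass
class TukeyComparison:
    group_i: int
    group_j: int
    mean_diff: float
    se: float
    q_stat: float
    p_value: float
    significant: bool


def tukey_hsd(groups: list, alpha: float = 0.05) -> list[TukeyComparison]:
    """Tukey's honestly-significant-difference pairwise comparisons.

    Uses SE = sqrt(MS_within * (1/n_i + 1/n_j) / 2) (the Tukey-Kramer
    convention, so q = |diff| / SE is on the studentized-range scale) and
    critical values from the exact studentized-range distribution at
    (n_groups, df_within).
    """
    anova = one_way_anova(groups)
    if anova.ms_within == 0:
        raise ValueError("zero within-group variance; Tukey HSD undefined")
    g = len(groups)
    q_crit = float(stats.studentized_range.ppf(1 - alpha, g, anova.df_within))
    out = []
    sizes = [len(gr) for gr in groups]
    for i in range(g):
        for j in range(i + 1, g):
            diff = anova.group_means[i] - anova.group_means[j]
            se = math.sqrt(anova.ms_within * (1 / sizes[i] + 1 / sizes[j]) / 2)
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, g, anova.df_within))
            out.append(TukeyComparison(i, j, diff, se, q, p, bool(q > q_crit)))
    return out
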