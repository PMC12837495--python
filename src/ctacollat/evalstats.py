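"""Evaluation framework: patient-level CV splits, ROC/AUC, Youden cut-off,
overall performance, confusion-rate arithmetic, and hyperparameter
comparison statistics.

Positive class = good (non-poor) collateral.  The headline metric is the
overall performance, the mean of the optimal Youden index
(sensitivity + specificity - 1, maximized over cut-offs) and the AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "FoldAssignment",
    "ROCResult",
    "PerformanceSummary",
    "assign_folds",
    "split_train_val",
    "roc_and_auc",
    "youden",
    "optimal_cutoff",
    "rates_to_counts",
    "overall_performance",
    "compare_groups",
    "orientation",
    "summarize_predictions",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Patient -> fold mapping for k-fold cross-validation."""

    folds: dict[str, int]
    k: int
    seed: int

    def patients_in(self, fold: int) -> list[str]:
        return [p for p, f in self.folds.items() if f == fold]


@dataclass(frozen=True)
class ROCResult:
    """ROC curve over all distinct thresholds plus the trapezoidal AUC."""

    thresholds: np.ndarray  # descending candidate cut-offs
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass(frozen=True)
class PerformanceSummary:
    """Threshold-level and threshold-free performance of one model."""

    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    optimal_youden: float
    overall_performance: float


def assign_folds(
    patients: list, k: int = 5, seed: int = 0, stratify: bool = True
) -> FoldAssignment:
    """Random balanced partition of patients into ``k`` folds.

    Stratified by class label by default so every test fold keeps both
    classes even with a 117:40 imbalance; fold sizes differ by at most 1.
    ``patients`` may be PatientRecords or (patient_id, label) pairs.
    """

    def _id_label(p):
        if hasattr(p, "patient_id"):
            return p.patient_id, p.label
        return p[0], p[1]

    pairs = [_id_label(p) for p in patients]
    ids = [pid for pid, _ in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    if len(pairs) < k:
        raise ValueError(f"need at least {k} patients, got {len(pairs)}")
    rng = np.random.default_rng(seed)
    folds: dict[str, int] = {}
    fold_sizes = np.zeros(k, dtype=int)
    groups: list[list[str]]
    if stratify:
        by_label: dict[object, list[str]] = {}
        for pid, lab in pairs:
            by_label.setdefault(lab, []).append(pid)
        # larger classes first so remainders even out across folds
        groups = [by_label[lab] for lab in sorted(by_label, key=lambda l: -len(by_label[l]))]
    else:
        groups = [ids]
    for group in groups:
        order = rng.permutation(len(group))
        chunks = np.array_split(order, k)  # sizes differ by <= 1, larger first
        # hand larger chunks to the currently smallest folds
        target = np.argsort(fold_sizes, kind="stable")
        for chunk, fold in zip(chunks, target):
            for j in chunk:
                folds[group[j]] = int(fold)
            fold_sizes[fold] += len(chunk)
    return FoldAssignment(folds=folds, k=k, seed=seed)


def split_train_val(
    patients: list, ratio: float = 0.25, seed: int = 0, stratify: bool = True
):
    """Patient-level 3:1 train/validation split of the training folds.

    Validation receives ``floor(n * ratio)`` patients; with
    stratification both classes appear in validation whenever both are
    present in the input.  Returns (train, val) lists in input order.
    """
    n = len(patients)
    n_val = int(np.floor(n * ratio))
    if n < 4 or n_val < 1 or n - n_val < 1:
        raise ValueError(f"cannot split {n} patients at ratio {ratio}")

    def _label(p):
        return p.label if hasattr(p, "label") else p[1]

    rng = np.random.default_rng(seed)
    idx = np.arange(n)
    labels = np.array([_label(p) for p in patients])
    val_idx: list[int] = []
    if stratify and len(np.unique(labels)) > 1:
        classes = sorted(np.unique(labels), key=lambda l: (labels == l).sum())
        remaining = n_val
        for ci, lab in enumerate(classes):
            cls_idx = idx[labels == lab]
            # at least one from each class, proportional otherwise
            quota = max(1, int(round(n_val * len(cls_idx) / n)))
            quota = min(quota, remaining - (len(classes) - 1 - ci)) if ci < len(classes) - 1 else remaining
            take = rng.permutation(cls_idx)[:quota]
            val_idx.extend(int(i) for i in take)
            remaining -= len(take)
    else:
        val_idx = [int(i) for i in rng.permutation(idx)[:n_val]]
    val_set = set(val_idx)
    train = [p for i, p in enumerate(patients) if i not in val_set]
    val = [p for i, p in enumerate(patients) if i in val_set]
    return train, val


def roc_and_auc(labels, probs) -> ROCResult:
    """ROC over all distinct thresholds with trapezoidal AUC.

    The trapezoidal area equals the Mann-Whitney formulation
    (#{pos > neg} + 0.5 #{ties}) / (n_pos * n_neg).
    """
    labels = np.asarray(labels)
    probs = np.asarray(probs, dtype=float)
    if labels.shape != probs.shape:
        raise ValueError("labels and probabilities differ in length")
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(labels, probs)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(
        thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr, auc=auc
    )


def youden(sensitivity: float, specificity: float) -> float:
    """Youden index J = sensitivity + specificity - 1."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return sensitivity + specificity - 1.0


def overall_performance(optimal_youden: float, auc: float) -> float:
    """Mean of the optimal Youden index and the AUC."""
    if not -1.0 <= optimal_youden <= 1.0:
        raise ValueError("Youden index outside [-1, 1]")
    if not 0.0 <= auc <= 1.0:
        raise ValueError("AUC outside [0, 1]")
    return (optimal_youden + auc) / 2.0


def optimal_cutoff(labels, probs) -> tuple[float, PerformanceSummary]:
    """Cut-off maximizing the Youden index, with the full summary.

    A patient is called positive when probability >= cutoff.  Ties in
    Youden are broken toward the cut-off with the higher sensitivity.
    """
    labels = np.asarray(labels)
    probs = np.asarray(probs, dtype=float)
    roc = roc_and_auc(labels, probs)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    candidates = np.unique(probs)
    best = None
    for c in candidates:
        pred = probs >= c
        sens = float((pred & pos).sum() / n_pos)
        spec = float((~pred & ~pos).sum() / n_neg)
        j = sens + spec - 1.0
        key = (j, sens)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    (_, _), cutoff, sens, spec = best
    j = youden(sens, spec)
    pred = probs >= cutoff
    acc = float((pred == pos).sum() / len(labels))
    summary = PerformanceSummary(
        auc=roc.auc,
        cutoff=float(cutoff),
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        optimal_youden=j,
        overall_performance=overall_performance(j, roc.auc),
    )
    return float(cutoff), summary


def rates_to_counts(
    sensitivity_pct: float, specificity_pct: float, n_pos: int, n_neg: int
) -> tuple[int, int, int, int, float]:
    """Recover confusion counts from printed percentage rates.

    Returns (TP, FN, TN, FP, accuracy).  Warns when the recovered integer
    count does not reproduce the printed rate at two-decimal precision,
    i.e. the rate is inconsistent with the stated cohort size.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("cohort sizes must be positive")
    tp = int(round(sensitivity_pct / 100.0 * n_pos))
    tn = int(round(specificity_pct / 100.0 * n_neg))
    for name, printed, count, n in (
        ("sensitivity", sensitivity_pct, tp, n_pos),
        ("specificity", specificity_pct, tn, n_neg),
    ):
        if abs(100.0 * count / n - printed) > 0.005 + 1e-9:
            warnings.warn(
                f"{name} {printed}% inconsistent with cohort size {n}", stacklevel=2
            )
    accuracy = (tp + tn) / (n_pos + n_neg)
    return tp, n_pos - tp, tn, n_neg - tn, accuracy


def orientation(summary: PerformanceSummary) -> float:
    """Signed sensitivity - specificity; positive = sensitivity-oriented."""
    return summary.sensitivity - summary.specificity


def compare_groups(
    results: pd.DataFrame,
    hyperparameter: str,
    paired: bool,
    value_col: str = "overall_performance",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise tests of a performance column between hyperparameter levels.

    Paired mode (full grid): a two-sided paired t-test per level pair,
    with observations matched on all remaining hyperparameter columns.
    Unpaired mode (e.g. an AUC-filtered subset): when either group has
    fewer than 30 observations and Shapiro-Wilk rejects normality at
    ``alpha``, a Mann-Whitney U test is used; otherwise an independent
    t-test (central-limit assumption for n >= 30).
    """
    hp_cols = [c for c in ("kernel_size", "first_filters", "n_conv", "fc_nodes", "batch_size") if c in results.columns]
    if hyperparameter not in hp_cols:
        raise ValueError(f"unknown hyperparameter column {hyperparameter!r}")
    levels = sorted(results[hyperparameter].unique())
    rows = []
    other = [c for c in hp_cols if c != hyperparameter]
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            ga = results[results[hyperparameter] == a]
            gb = results[results[hyperparameter] == b]
            if paired:
                merged = ga.merge(gb, on=other, suffixes=("_a", "_b"))
                if len(merged) < len(ga) or len(merged) < len(gb):
                    missing = max(len(ga), len(gb)) - len(merged)
                    raise ValueError(
                        f"paired comparison {a} vs {b}: {missing} unmatched configurations"
                    )
                xa = merged[f"{value_col}_a"].to_numpy(float)
                xb = merged[f"{value_col}_b"].to_numpy(float)
                if np.allclose(xa, xb):
                    stat, p = 0.0, 1.0
                else:
                    stat, p = stats.ttest_rel(xa, xb)
                test, normal_p = "paired t", None
            else:
                xa = ga[value_col].to_numpy(float)
                xb = gb[value_col].to_numpy(float)
                if len(xa) < 2 or len(xb) < 2:
                    raise ValueError("each group needs >= 2 observations")
                normal_p = None
                nonnormal = False
                if min(len(xa), len(xb)) < 30:
                    ps = [stats.shapiro(x).pvalue for x in (xa, xb) if len(x) < 30]
                    normal_p = min(ps)
                    nonnormal = normal_p < alpha
                if nonnormal:
                    stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
                    test = "Mann-Whitney U"
                else:
                    stat, p = stats.ttest_ind(xa, xb)
                    test = "independent t"
            rows.append(
                {
                    "hyperparameter": hyperparameter,
                    "level_a": a,
                    "level_b": b,
                    "test": test,
                    "statistic": float(stat),
                    "p_value": float(p),
                    "shapiro_min_p": normal_p,
                    "n_a": len(ga),
                    "n_b": len(gb),
                }
            )
    return pd.DataFrame(rows)


def summarize_predictions(labels, probs) -> PerformanceSummary:
    """Pooled-probability PerformanceSummary (ROC, Youden cut-off, overall performance)."""
    _, summary = optimal_cutoff(labels, probs)
    return summary
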