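"""Validation statistics: splits, rank correlation, ROC analysis, model tests.

Everything here operates on plain numpy arrays so it can serve both the
cascade trainer (internal 2:1:1 holdout, Spearman screening) and external
model evaluation (10-fold cross-validation, AUROC for the inhibitor and
multi-inhibitor tasks, Youden-optimal thresholds, paired AUC comparison by
DeLong's method, accuracy, chi-squared contingency tests).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class Partition:
    """Group assignment of n items; groups are exclusive and exhaustive."""

    assignments: np.ndarray  # group index per item
    scheme: str  # "holdout_2_1_1" | "kfold"
    seed: int
    n_groups: int

    def group(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == g)

    def sizes(self) -> list[int]:
        return [int(np.sum(self.assignments == g)) for g in range(self.n_groups)]

    def folds(self):
        """Yield (train_idx, test_idx) pairs, one per group held out."""
        for g in range(self.n_groups):
            test = self.group(g)
            train = np.flatnonzero(self.assignments != g)
            yield train, test


@dataclass
class RocResult:
    """ROC curve summary for one dichotomization of the graded outcome."""

    auroc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    positive_definition: str = "inhibitor_task"
    scores: np.ndarray = field(default=None, repr=False)
    labels: np.ndarray = field(default=None, repr=False)


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    method: str


def _quota_sizes(n: int, ratio: tuple[int, ...]) -> list[int]:
    # largest-remainder apportionment; remainder ties go to earlier groups
    total = sum(ratio)
    quotas = [n * r / total for r in ratio]
    sizes = [int(math.floor(q)) for q in quotas]
    leftovers = n - sum(sizes)
    order = sorted(range(len(ratio)), key=lambda i: (-(quotas[i] - sizes[i]), i))
    for i in order[:leftovers]:
        sizes[i] += 1
    return sizes


def holdout_split(n: int, ratio: tuple[int, ...] = (2, 1, 1), seed: int = 0) -> Partition:
    """Random train/verification/testing split in the given ratio (default 2:1:1).

    Sizes follow largest-remainder rounding with ties resolved in group order,
    so the training subset absorbs remainders first.
    """
    if n < sum(ratio) or n < 8:
        raise ValueError(f"n={n} too small for a {ratio} split")
    sizes = _quota_sizes(n, ratio)
    perm = np.random.default_rng(seed).permutation(n)
    assign = np.empty(n, dtype=int)
    start = 0
    for g, s in enumerate(sizes):
        assign[perm[start : start + s]] = g
        start += s
    return Partition(assign, "holdout_2_1_1", seed, len(ratio))


def kfold_split(n: int, k: int = 10, seed: int = 0) -> Partition:
    """Random k-fold partition into mutually exclusive groups of near-equal size."""
    if n < k:
        raise ValueError(f"n={n} < k={k}")
    perm = np.random.default_rng(seed).permutation(n)
    assign = np.empty(n, dtype=int)
    base, extra = divmod(n, k)
    start = 0
    for g in range(k):
        s = base + (1 if g < extra else 0)
        assign[perm[start : start + s]] = g
        start += s
    return Partition(assign, "kfold", seed, k)


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman(x, y) -> ComparisonResult:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    The p-value uses the t approximation for n > 9 and an exact permutation
    enumeration for n <= 9 (two-sided in both cases).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input vector")
    rx, ry = _midranks(x), _midranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        # enumerate all pairings of the observed rank vectors
        perms = np.array(list(itertools.permutations(range(n))))
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
        rhos = (ry_c[perms] @ rx_c) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho * rho))
            p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return ComparisonResult(rho, p, "spearman")


def spearman_rho(x, y) -> float:
    """Rank correlation coefficient only (no p-value); fast path for screening."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx, ry = _midranks(x), _midranks(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(((rx - rx.mean()) @ (ry - ry.mean())) / (x.size * sx * sy))


def dichotomize(counts, task: str) -> np.ndarray:
    """Binary labels from inhibited-isoform counts.

    ``inhibitor_task``: positives inhibit at least one isoform (count >= 1).
    ``multi_task``: positives inhibit at least three (count >= 3).
    """
    counts = np.asarray(counts)
    if task == "inhibitor_task":
        return (counts >= 1).astype(int)
    if task == "multi_task":
        return (counts >= 3).astype(int)
    raise ValueError(f"unknown task {task!r}")


def auroc(scores, binary_labels, positive_definition: str = "inhibitor_task") -> RocResult:
    """ROC analysis of scores against binary labels.

    The AUROC is the Mann-Whitney pair statistic: the fraction of
    (positive, negative) pairs where the positive outscores the negative,
    ties counted one half.  Curve points are evaluated at thresholds midway
    between consecutive distinct scores (plus sentinels beyond the extremes),
    predicting positive for score > threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(binary_labels, dtype=int)
    npos = int(labels.sum())
    nneg = labels.size - npos
    if npos == 0 or nneg == 0:
        raise ValueError("both classes must be present")
    ranks = _midranks(scores)
    auc = (ranks[labels == 1].sum() - npos * (npos + 1) / 2) / (npos * nneg)
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2 if uniq.size > 1 else np.array([])
    thresholds = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    sens = np.array([(scores[labels == 1] > t).mean() for t in thresholds])
    spec = np.array([(scores[labels == 0] <= t).mean() for t in thresholds])
    return RocResult(float(auc), thresholds, sens, spec, positive_definition, scores, labels)


def youden_threshold(roc: RocResult) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties resolve to the lowest threshold.  For perfectly separated scores
    this lands midway inside the separating gap.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    return float(roc.thresholds[int(np.argmax(j))])


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_r = _midranks(np.concatenate([pos, neg]))
    pos_r = _midranks(pos)
    neg_r = _midranks(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n           # structural components, positives
    v01 = 1.0 - (all_r[m:] - neg_r) / m     # structural components, negatives
    return auc, v10, v01


def compare_auroc(scores_a, scores_b, binary_labels) -> ComparisonResult:
    """Paired comparison of two AUROCs on the same compounds (DeLong test).

    The covariance of the two empirical AUCs is estimated from the paired
    structural components; the statistic is the normal z for the AUC
    difference, with a two-sided p-value.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(binary_labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("inputs must be aligned")
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("both classes must be present")
    auc_a, v10a, v01a = _delong_components(scores_a, labels)
    auc_b, v10b, v01b = _delong_components(scores_b, labels)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0 if diff == 0 else math.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / math.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
    return ComparisonResult(float(z), p, "correlated_roc")


def accuracy(predicted_calls, true_calls) -> float:
    """Fraction of compounds whose predicted call matches the true call."""
    pred = np.asarray(predicted_calls)
    true = np.asarray(true_calls)
    if pred.shape != true.shape:
        raise ValueError("length mismatch")
    return float(np.mean(pred == true))


def chisq_2x2(table, correction: bool = False, method: str = "pearson") -> ComparisonResult:
    """Chi-squared test on a 2x2 contingency table (df = 1, two-sided).

    Default is Pearson's statistic without continuity correction;
    ``method='mcnemar'`` gives the paired (McNemar) test on the
    discordant cells instead.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a nonnegative 2x2 table")
    if method == "mcnemar":
        b, c = t[0, 1], t[1, 0]
        if b + c == 0:
            return ComparisonResult(0.0, 1.0, "chi_squared")
        stat = (abs(b - c) - (1.0 if correction else 0.0)) ** 2 / (b + c)
        return ComparisonResult(float(stat), float(sps.chi2.sf(stat, df=1)), "chi_squared")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal")
    stat, p, _, _ = sps.chi2_contingency(t, correction=correction)
    return ComparisonResult(float(stat), float(p), "chi_squared")
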