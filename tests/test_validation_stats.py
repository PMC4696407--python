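import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from p450nnc import (
    accuracy,
    auroc,
    chisq_2x2,
    compare_auroc,
    dichotomize,
    holdout_split,
    kfold_split,
    spearman,
    youden_threshold,
)


# ---------------------------------------------------------------- oracles

def rank_then_pearson(x, y):
    """Independent Spearman oracle: hand-computed mid-ranks, then Pearson."""
    def midrank(v):
        v = np.asarray(v, float)
        r = np.empty(len(v))
        for i, vi in enumerate(v):
            less = np.sum(v < vi)
            ties = np.sum(v == vi)
            r[i] = less + (ties + 1) / 2
        return r
    rx, ry = midrank(x), midrank(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def pair_count_auroc(scores, labels):
    """O(n^2) Mann-Whitney oracle: fraction of positive>negative pairs."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


# ---------------------------------------------------------------- spearman

def test_spearman_perfect_and_reversed():
    x = np.arange(10.0)
    assert spearman(x, x**3).statistic == pytest.approx(1.0)
    assert spearman(x, -x).statistic == pytest.approx(-1.0)


def test_spearman_matches_oracle_with_ties(rng):
    x = rng.integers(0, 8, 20).astype(float)
    y = rng.integers(0, 8, 20).astype(float)
    assert spearman(x, y).statistic == pytest.approx(rank_then_pearson(x, y), abs=1e-12)


def test_spearman_exact_small_n_p_value():
    """For n <= 9 the p-value is the exact permutation tail probability."""
    x = [1, 2, 3, 4, 5]
    y = [2, 1, 4, 3, 5]
    res = spearman(x, y)
    ref = sps.spearmanr(x, y)
    assert res.statistic == pytest.approx(ref.statistic)
    # exact two-sided permutation p for n=5
    import itertools, math
    rx = np.array(x, float)
    count = 0
    rho_obs = res.statistic
    for perm in itertools.permutations(range(5)):
        r = np.corrcoef(rx, np.array(y, float)[list(perm)])[0, 1]
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    assert res.p_value == pytest.approx(count / math.factorial(5), abs=1e-12)


def test_spearman_errors():
    with pytest.raises(ValueError):
        spearman([1, 2], [1, 2])
    with pytest.raises(ValueError):
        spearman([1, 1, 1, 1], [1, 2, 3, 4])


# ---------------------------------------------------------------- splits

def test_holdout_sizes():
    assert holdout_split(8, seed=0).sizes() == [4, 2, 2]
    # largest-remainder with ties going to the earliest group: verification
    # takes the leftover before testing
    assert holdout_split(10, seed=0).sizes() == [5, 3, 2]
    assert sum(holdout_split(997, seed=1).sizes()) == 997


def test_holdout_reproducible_and_bounds():
    a = holdout_split(50, seed=7)
    b = holdout_split(50, seed=7)
    assert np.array_equal(a.assignments, b.assignments)
    with pytest.raises(ValueError):
        holdout_split(5)


def test_kfold_8148():
    sizes = sorted(kfold_split(8148, 10, seed=0).sizes())
    assert sizes == [814, 814] + [815] * 8


def test_kfold_folds_cover_everything():
    part = kfold_split(10, 10, seed=3)
    assert sorted(part.sizes()) == [1] * 10  # leave-one-out
    seen = []
    for train, test in part.folds():
        assert len(np.intersect1d(train, test)) == 0
        seen.extend(test.tolist())
    assert sorted(seen) == list(range(10))


@given(
    st.integers(min_value=12, max_value=10_000),
    st.integers(min_value=2, max_value=12),
)
@settings(max_examples=60, deadline=None)
def test_partition_invariants_sweep(n, k):
    if n < k:
        n = k
    part = kfold_split(n, k, seed=11)
    sizes = part.sizes()
    assert sum(sizes) == n
    assert max(sizes) - min(sizes) <= 1
    hold = holdout_split(max(n, 8), seed=11)
    assert sum(hold.sizes()) == max(n, 8)


# ---------------------------------------------------------------- ROC

def test_auroc_separated_and_degenerate():
    y = np.array([0, 0, 0, 1, 1, 1])
    assert auroc(np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9]), y).auroc == 1.0
    assert auroc(np.full(6, 0.5), y).auroc == 0.5
    with pytest.raises(ValueError):
        auroc(np.arange(4.0), np.ones(4, dtype=int))


def test_auroc_matches_pair_count_oracle(rng):
    scores = np.round(rng.uniform(0, 1, 80), 1)  # coarse grid forces ties
    labels = rng.integers(0, 2, 80)
    labels[:2] = [0, 1]
    assert auroc(scores, labels).auroc == pytest.approx(
        pair_count_auroc(scores, labels), abs=1e-12
    )


def test_auroc_invariant_under_monotone_transform(rng):
    scores = rng.normal(size=100)
    labels = rng.integers(0, 2, 100)
    labels[:2] = [0, 1]
    a = auroc(scores, labels).auroc
    b = auroc(np.exp(3 * scores) + 7, labels).auroc
    assert a == pytest.approx(b, abs=1e-12)


def test_dichotomize_tasks_share_scores():
    counts = np.array([0, 1, 2, 3, 4, 5])
    assert np.array_equal(dichotomize(counts, "inhibitor_task"), [0, 1, 1, 1, 1, 1])
    assert np.array_equal(dichotomize(counts, "multi_task"), [0, 0, 0, 1, 1, 1])
    with pytest.raises(ValueError):
        dichotomize(counts, "other")


def test_youden_threshold_matches_exhaustive_search(rng):
    scores = np.round(rng.uniform(0, 1, 10), 2)
    labels = rng.integers(0, 2, 10)
    labels[:2] = [0, 1]
    roc = auroc(scores, labels)
    t = youden_threshold(roc)
    # brute force over a fine grid of candidate cuts
    def j(thresh):
        sens = np.mean(scores[labels == 1] > thresh)
        spec = np.mean(scores[labels == 0] <= thresh)
        return sens + spec - 1
    grid = np.linspace(scores.min() - 1, scores.max() + 1, 5001)
    assert j(t) == pytest.approx(max(j(g) for g in grid), abs=1e-12)


def test_youden_perfect_separation_midpoint():
    scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
    labels = np.array([0, 0, 0, 1, 1, 1])
    t = youden_threshold(auroc(scores, labels))
    assert t == pytest.approx(0.5)  # midpoint of the separating gap


def test_youden_tie_takes_lower_threshold():
    scores = np.array([0.2, 0.4, 0.6, 0.8])
    labels = np.array([0, 1, 0, 1])
    roc = auroc(scores, labels)
    t = youden_threshold(roc)
    j = roc.sensitivity + roc.specificity - 1
    best = j.max()
    candidates = roc.thresholds[j == best]
    assert t == candidates.min()


# ---------------------------------------------------------------- DeLong

def test_compare_auroc_identical_scores(rng):
    y = rng.integers(0, 2, 60)
    y[:2] = [0, 1]
    s = rng.normal(size=60)
    res = compare_auroc(s, s, y)
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_compare_auroc_variance_matches_bootstrap(rng):
    """DeLong variance of the paired AUC difference agrees with a seeded
    10,000-replicate paired bootstrap within 15% relative error."""
    from p450nnc.validation_stats import _delong_components

    n = 150
    y = rng.integers(0, 2, n)
    y[:2] = [0, 1]
    a = y + rng.normal(0, 1.2, n)
    b = y + rng.normal(0, 1.5, n)
    auc_a, v10a, v01a = _delong_components(a, y)
    auc_b, v10b, v01b = _delong_components(b, y)
    m, k = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = s10 / m + s01 / k
    var_d = var[0, 0] + var[1, 1] - 2 * var[0, 1]
    diffs = []
    for _ in range(10_000):
        idx = rng.integers(0, n, n)
        yy = y[idx]
        if yy.sum() in (0, n):
            continue
        diffs.append(auroc(a[idx], yy).auroc - auroc(b[idx], yy).auroc)
    bv = np.var(diffs)
    assert abs(var_d - bv) / bv < 0.15


def test_compare_auroc_p_uniform_under_null(rng):
    """Under label permutation the DeLong p-value is approximately uniform."""
    n = 120
    y = rng.integers(0, 2, n)
    y[:2] = [0, 1]
    a = rng.normal(size=n)
    b = 0.5 * a + rng.normal(size=n)
    ps = [compare_auroc(a, b, rng.permutation(y)).p_value for _ in range(500)]
    assert sps.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------- counts

def test_accuracy():
    assert accuracy([1, 1, 0, 0], [1, 1, 0, 0]) == 1.0
    assert accuracy([1, 1, 0, 1], [1, 1, 0, 0]) == 0.75
    with pytest.raises(ValueError):
        accuracy([1, 0], [1, 0, 1])


def test_accuracy_from_confusion_table():
    tp, tn, fp, fn = 30, 40, 10, 20
    pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
    true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
    assert accuracy(pred, true) == pytest.approx((tp + tn) / (tp + tn + fp + fn))


def test_chisq_2x2_uniform_and_hand_computed():
    res = chisq_2x2([[10, 10], [10, 10]])
    assert res.statistic == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)
    # hand computation for [[30,20],[10,40]]
    table = np.array([[30, 20], [10, 40]], float)
    n = table.sum()
    expected = np.outer(table.sum(1), table.sum(0)) / n
    stat = float(((table - expected) ** 2 / expected).sum())
    assert chisq_2x2(table).statistic == pytest.approx(stat, abs=1e-10)
    # symmetric under row swap
    assert chisq_2x2(table[::-1]).statistic == pytest.approx(stat, abs=1e-10)


def test_chisq_equals_squared_proportion_z():
    """Pearson chi-square on a 2x2 table equals the squared two-proportion z."""
    t = np.array([[18, 7], [12, 23]], float)
    n1, n2 = t[0].sum(), t[1].sum()
    p1, p2 = t[0, 0] / n1, t[1, 0] / n2
    p = (t[0, 0] + t[1, 0]) / (n1 + n2)
    z = (p1 - p2) / np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
    assert chisq_2x2(t).statistic == pytest.approx(z**2, abs=1e-10)


def test_chisq_errors_and_mcnemar():
    with pytest.raises(ValueError):
        chisq_2x2([[0, 0], [5, 5]])
    res = chisq_2x2([[10, 6], [2, 10]], method="mcnemar")
    assert res.statistic == pytest.approx((6 - 2) ** 2 / 8)
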