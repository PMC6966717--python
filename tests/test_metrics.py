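import itertools
import math

import numpy as np
import pytest

from pairscreen import (
    ConfusionCounts,
    compare_runs,
    confusion,
    curve_area,
    full_report,
    metrics,
    pr_points,
    repeat_summary,
    roc_points,
)


def roc_auc_pair_counting(labels, scores):
    """Mann-Whitney oracle: concordant (pos, neg) pairs, ties counted 1/2."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def test_confusion_worked_examples():
    c = confusion([1, 0], [0.9, 0.1])
    assert (c.TP, c.TN, c.FP, c.FN) == (1, 1, 0, 0)
    # strict '>' at the cutoff: exact ties predict negative
    c = confusion([1, 0, 1], [0.5, 0.5, 0.5], cutoff=0.5)
    assert c.TP == 0 and c.FP == 0 and c.TN == 1 and c.FN == 2


def test_confusion_matches_per_record_tally(rng):
    y = (rng.random(50) < 0.5).astype(int)
    p = rng.random(50)
    c = confusion(y, p, cutoff=0.4)
    tally = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    for yi, pi in zip(y, p):
        pred = pi > 0.4
        key = ("T" if (pred == yi) else "F") + ("P" if pred else "N")
        tally[key] += 1
    assert (c.TP, c.FP, c.TN, c.FN) == (
        tally["TP"], tally["FP"], tally["TN"], tally["FN"]
    )
    assert c.total == 50


def test_confusion_length_mismatch():
    with pytest.raises(ValueError):
        confusion([1, 0], [0.5])


def test_metrics_perfect_classifier():
    rep = metrics(ConfusionCounts(TP=50, FP=0, TN=50, FN=0))
    assert (rep.AC, rep.SE, rep.SP, rep.PR, rep.MCC) == (100, 100, 100, 100, 1)


def test_metrics_worked_example_exact_arithmetic():
    rep = metrics(ConfusionCounts(TP=40, FN=10, TN=45, FP=5))
    assert rep.AC == pytest.approx(85.0)
    assert rep.SE == pytest.approx(80.0)
    assert rep.SP == pytest.approx(90.0)
    assert rep.PR == pytest.approx(100 * 40 / 45)
    expected_mcc = (40 * 45 - 5 * 10) / math.sqrt(45 * 50 * 50 * 55)
    assert rep.MCC == pytest.approx(expected_mcc)
    assert rep.MCC == pytest.approx(0.7035, abs=5e-5)


def test_mcc_symmetries():
    a = metrics(ConfusionCounts(TP=40, FN=10, TN=45, FP=5))
    # exchanging the roles of the two classes (TP<->TN, FP<->FN) leaves
    # both AC and MCC unchanged
    swapped = metrics(ConfusionCounts(TP=45, FN=5, TN=40, FP=10))
    assert swapped.MCC == pytest.approx(a.MCC)
    assert swapped.AC == pytest.approx(a.AC)
    # flipping the ground-truth labels against fixed predictions negates MCC
    flipped = metrics(ConfusionCounts(TP=5, FP=40, TN=10, FN=45))
    assert flipped.MCC == pytest.approx(-a.MCC)


def test_undefined_ratios_reported_absent_not_zero():
    rep = metrics(ConfusionCounts(TP=0, FP=0, TN=10, FN=0))
    assert rep.SE is None      # no positives
    assert rep.PR is None      # nothing predicted positive
    assert rep.MCC is None
    assert rep.AC == 100.0
    with pytest.raises(ValueError):
        metrics(ConfusionCounts(0, 0, 0, 0))


def test_roc_perfect_and_reversed():
    y = [1, 1, 0, 0]
    assert curve_area(roc_points(y, [0.9, 0.8, 0.2, 0.1])) == pytest.approx(1.0)
    assert curve_area(pr_points(y, [0.9, 0.8, 0.2, 0.1])) == pytest.approx(1.0)
    roca = curve_area(roc_points(y, [0.3, 0.6, 0.5, 0.1]))
    reversed_roca = curve_area(roc_points(y, [1 - s for s in [0.3, 0.6, 0.5, 0.1]]))
    assert reversed_roca == pytest.approx(1 - roca)


def test_roc_worked_example_three_quarters():
    assert curve_area(
        roc_points([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1])
    ) == pytest.approx(0.75)


@pytest.mark.parametrize("seed", range(10))
def test_roca_equals_pair_counting_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 40))
    y = np.zeros(n, dtype=int)
    y[: n // 2] = 1
    rng.shuffle(y)
    scores = np.round(rng.random(n), 2)  # rounding creates ties
    assert curve_area(roc_points(y, scores)) == pytest.approx(
        roc_auc_pair_counting(y, scores), abs=1e-10
    )


def test_single_class_curves_rejected():
    with pytest.raises(ValueError):
        roc_points([1, 1], [0.5, 0.6])
    with pytest.raises(ValueError):
        pr_points([0, 0], [0.5, 0.6])


def test_cutoff_sweep_matches_roc_point(rng):
    y = (rng.random(30) < 0.5).astype(int)
    s = rng.random(30)
    pts = roc_points(y, s)
    for cutoff in np.unique(s):
        c = confusion(y, s, cutoff=cutoff)
        fpr = c.FP / (c.FP + c.TN)
        tpr = c.TP / (c.TP + c.FN)
        assert any(
            abs(fpr - x) < 1e-12 and abs(tpr - yy) < 1e-12 for x, yy in pts
        )


def test_repeat_summary():
    s = repeat_summary([10, 10, 10])
    assert (s.mean, s.rsd) == (10.0, 0.0)
    s = repeat_summary([9, 11])
    assert s.mean == 10.0
    assert s.rsd == pytest.approx(100 * math.sqrt(2) / 10)
    a = repeat_summary([3.0, 4.0, 5.5])
    b = repeat_summary([30.0, 40.0, 55.0])
    assert a.rsd == pytest.approx(b.rsd)
    with pytest.raises(ValueError):
        repeat_summary([1.0])


def rank_sum_exact_p(x, y):
    """Exhaustive permutation distribution of the rank-sum statistic."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # no ties by construction
    observed = sum(ranks[v] for v in x)
    n = len(x)
    sums = [
        sum(combo)
        for combo in itertools.combinations([ranks[v] for v in pooled], n)
    ]
    mean = np.mean(sums)
    extreme = sum(1 for s in sums if abs(s - mean) >= abs(observed - mean) - 1e-9)
    return extreme / len(sums)


def test_compare_runs_identical_samples_give_maximal_p():
    out = compare_runs([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    assert out["p_ranksum"] == pytest.approx(1.0)
    assert out["p_ks"] == pytest.approx(1.0)


def test_compare_runs_matches_exact_permutation_enumeration():
    x = [1.1, 2.3, 3.1, 4.7, 5.2]
    y = [0.4, 1.9, 2.8, 3.6, 6.0]
    out = compare_runs(x, y)
    assert out["p_ranksum"] == pytest.approx(rank_sum_exact_p(x, y), abs=1e-9)


def test_compare_runs_is_symmetric():
    x = [1.0, 5.0, 3.0, 8.0]
    y = [2.0, 9.0, 4.0, 7.0]
    assert compare_runs(x, y) == compare_runs(y, x)


def test_compare_runs_degenerate_all_tied_warns():
    with pytest.warns(UserWarning):
        out = compare_runs([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
    assert out == {"p_ranksum": None, "p_ks": None}


def test_compare_runs_requires_three_values():
    with pytest.raises(ValueError):
        compare_runs([1.0, 2.0], [1.0, 2.0, 3.0])


def test_full_report_combines_point_and_curve_metrics(rng):
    y = np.array([1, 1, 0, 0, 1, 0])
    p = np.array([0.9, 0.7, 0.6, 0.2, 0.8, 0.1])
    rep = full_report(y, p)
    assert rep.AC is not None and rep.ROCA is not None and rep.PRCA is not None
    assert 0 <= rep.ROCA <= 1 and 0 <= rep.PRCA <= 1
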