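import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from episcan.diagnostics import (
    ConfusionCounts,
    clopper_pearson,
    evaluate,
    likelihood_ratios,
    mcc,
    optimal_cutoff_by_mcc,
    rank_sum_test,
    roc_auc,
    roc_curve,
)


@pytest.mark.parametrize(
    "counts, expected",
    [
        (ConfusionCounts(10, 0, 0, 10), 1.0),
        (ConfusionCounts(5, 5, 5, 5), 0.0),
        (ConfusionCounts(19, 7, 12, 40), 0.482),
    ],
)
def test_mcc_values(counts, expected):
    assert mcc(counts) == pytest.approx(expected, abs=5e-4)


def test_mcc_zero_margin_convention():
    with pytest.warns(UserWarning):
        assert mcc(ConfusionCounts(0, 0, 5, 5)) == 0.0


counts_strategy = st.tuples(*[st.integers(1, 50)] * 4)


@given(counts_strategy)
def test_mcc_symmetries(tpl):
    tp, fp, fn, tn = tpl
    c = ConfusionCounts(tp, fp, fn, tn)
    swapped = ConfusionCounts(tn, fn, fp, tp)     # swap classes and predictions
    flipped = ConfusionCounts(fn, tn, tp, fp)     # flip every prediction
    assert mcc(swapped) == pytest.approx(mcc(c))
    assert mcc(flipped) == pytest.approx(-mcc(c))


def test_optimal_cutoff_separable():
    scores = [0, 1, 2, 3, 4]
    labels = ["control", "control", "case", "case", "case"]
    cutoff, cc, best = optimal_cutoff_by_mcc(scores, labels)
    assert 1 < cutoff < 2
    assert best == 1.0
    assert (cc.tp, cc.fp, cc.fn, cc.tn) == (3, 0, 0, 2)


def test_optimal_cutoff_matches_bruteforce():
    rng = np.random.default_rng(99)
    scores = rng.normal(size=50) + np.repeat([0.0, 1.0], 25)
    labels = np.repeat(["control", "case"], 25)
    cutoff, _, best = optimal_cutoff_by_mcc(scores, labels)
    lab = labels == "case"
    mids = np.unique(scores)
    mids = (mids[:-1] + mids[1:]) / 2
    brute = max(
        mcc(ConfusionCounts(
            int(((scores > c) & lab).sum()), int(((scores > c) & ~lab).sum()),
            int((~(scores > c) & lab).sum()), int((~(scores > c) & ~lab).sum()),
        ))
        for c in mids
    )
    assert best == pytest.approx(brute)
    with pytest.raises(ValueError):
        optimal_cutoff_by_mcc([1.0, 1.0], ["case", "control"])
    with pytest.raises(ValueError):
        optimal_cutoff_by_mcc([1.0, 2.0], ["case", "case"])


def test_permuted_labels_give_near_zero_mcc():
    rng = np.random.default_rng(7)
    scores = rng.normal(size=40)
    best_vals = []
    for _ in range(200):
        labels = rng.permutation(np.repeat(["case", "control"], 20))
        _, _, best = optimal_cutoff_by_mcc(scores, labels)
        best_vals.append(best)
    # optimization inflates |MCC| above 0, but it stays modest under the null
    assert 0 < np.mean(np.abs(best_vals)) < 0.45


def test_auc_values_and_pair_enumeration():
    assert roc_auc([1, 2, 3, 4], ["control", "control", "case", "case"]) == 1.0
    # pairs: 3>2, 3>0, 1<2, 1>0 -> 3 of 4
    assert roc_auc([3, 1, 2, 0], ["case", "case", "control", "control"]) == 0.75
    rng = np.random.default_rng(1)
    s = rng.normal(size=400)
    labels = np.repeat(["case", "control"], 200)
    assert roc_auc(s, labels) == pytest.approx(0.5, abs=0.08)


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=20)
def test_auc_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    s = rng.normal(size=30)
    labels = rng.permutation(np.repeat(["case", "control"], 15))
    a = roc_auc(s, labels)
    assert roc_auc(np.exp(s), labels) == pytest.approx(a)
    assert roc_auc(3 * s + 7, labels) == pytest.approx(a)


def test_roc_curve_monotone():
    rng = np.random.default_rng(3)
    s = rng.normal(size=60)
    labels = np.repeat(["case", "control"], 30)
    pts = roc_curve(s, labels)
    assert (np.diff(pts["fpr"]) >= 0).all()
    assert (np.diff(pts["tpr"]) >= 0).all()
    assert pts.iloc[0]["tpr"] == 0.0 and pts.iloc[-1]["tpr"] == 1.0


@pytest.mark.parametrize(
    "successes, n, expected",
    [
        (19, 31, (0.42, 0.78)),  # reported assay sensitivity interval
        (40, 47, (0.72, 0.94)),  # reported assay specificity interval
    ],
)
def test_clopper_pearson_reported_intervals(successes, n, expected):
    lo, hi = clopper_pearson(successes, n)
    assert (round(lo, 2), round(hi, 2)) == expected


def test_clopper_pearson_boundaries_and_nesting():
    lo, hi = clopper_pearson(0, 10)
    assert lo == 0.0
    assert clopper_pearson(10, 10)[1] == 1.0
    for s, n in [(0, 10), (3, 17), (19, 31), (47, 47)]:
        lo95, hi95 = clopper_pearson(s, n, 0.95)
        lo99, hi99 = clopper_pearson(s, n, 0.99)
        assert lo99 <= lo95 and hi99 >= hi95


def test_likelihood_ratios_hand_values():
    counts = ConfusionCounts(19, 7, 12, 40)
    (lrp, lrp_lo, lrp_hi), (lrm, lrm_lo, lrm_hi) = likelihood_ratios(counts)
    assert lrp == pytest.approx(4.12, abs=0.005)
    assert lrm == pytest.approx(0.45, abs=0.005)
    assert lrp_lo < lrp < lrp_hi
    assert lrm_lo < lrm < lrm_hi
    # uninformative test
    (lrp, *_), (lrm, *_) = likelihood_ratios(ConfusionCounts(5, 5, 5, 5))
    assert lrp == pytest.approx(1.0) and lrm == pytest.approx(1.0)
    # increasing TP at fixed margins raises LR+
    (lrp2, *_), _ = likelihood_ratios(ConfusionCounts(25, 7, 6, 40))
    assert lrp2 > 4.12
    # perfect specificity
    (lrp3, _, hi3), _ = likelihood_ratios(ConfusionCounts(5, 0, 5, 10))
    assert np.isinf(lrp3) and np.isinf(hi3)


def test_rank_sum_exact_enumeration():
    _, p = rank_sum_test([1, 2, 3], [4, 5, 6])
    assert p == pytest.approx(0.1)  # U = 0, 2 x 1/20
    _, p_same = rank_sum_test([1.0, 2.0], [1.0, 2.0])
    assert p_same == 1.0


def test_rank_sum_exact_vs_asymptotic_agree():
    rng = np.random.default_rng(12)
    x = rng.normal(size=15)
    y = rng.normal(size=15) + 0.5
    _, p_exact = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    _, p_ours = rank_sum_test(x, y)  # n = 30 -> asymptotic path
    assert p_ours == pytest.approx(p_exact, abs=0.01)


def test_evaluate_recovers_generating_discrimination():
    """End-to-end cohort evaluation on synthetic mixed-peptide scores."""
    rng = np.random.default_rng(2024)
    n_case, n_control = 31, 47
    scores = np.concatenate([
        rng.normal(1.2, 0.6, n_case),     # cases higher on OD scale
        rng.normal(0.5, 0.4, n_control),
    ])
    labels = np.repeat(["case", "control"], [n_case, n_control])
    out = evaluate(scores, labels)
    # generating separation ~0.81 AUC (Phi(0.7/sqrt(0.52)))
    assert out.auc == pytest.approx(0.83, abs=0.1)
    assert out.counts.tp + out.counts.fn == n_case
    assert out.counts.tn + out.counts.fp == n_control
    assert out.sensitivity_ci[0] < out.sensitivity < out.sensitivity_ci[1]
    assert out.rank_test_p < 1e-3
    assert -1 <= out.mcc <= 1 and 0 <= out.auc <= 1
    row = out.to_frame().iloc[0]
    assert row["cutoff"] == out.cutoff


def test_cutoff_recovery_on_synthetic_cohort():
    """Sens/spec at the MCC-optimal cutoff sit near the generating values."""
    rng = np.random.default_rng(55)
    mu_case, mu_ctrl, sd = 1.4, 0.6, 0.35
    scores = np.concatenate([
        rng.normal(mu_case, sd, 120), rng.normal(mu_ctrl, sd, 120)
    ])
    labels = np.repeat(["case", "control"], 120)
    out = evaluate(scores, labels)
    mid = (mu_case + mu_ctrl) / 2
    expected = stats.norm.cdf((mu_case - mid) / sd)
    assert out.sensitivity == pytest.approx(expected, abs=0.1)
    assert out.specificity == pytest.approx(expected, abs=0.1)
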