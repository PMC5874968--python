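"""Evaluation of a diagnostic ELISA separating cases from controls.

Implements the standard toolkit for a continuous-readout binary test:
cutoff optimization by Matthews correlation coefficient (MCC), ROC/AUC via
the Mann-Whitney identity, exact Clopper-Pearson binomial intervals for
sensitivity and specificity, likelihood ratios with log-scale delta-method
intervals, and the Wilcoxon rank-sum comparison of the two score
distributions.  Cases are assumed to score higher; a sample is predicted
positive when its score exceeds the cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 (with a warning) if a margin is empty."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        warnings.warn("a confusion-matrix margin is zero; MCC set to 0")
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom2)


def _confusion_at(scores: np.ndarray, labels: np.ndarray,
                  cutoff: float) -> ConfusionCounts:
    pred = scores > cutoff
    return ConfusionCounts(
        tp=int(np.sum(pred & labels)),
        fp=int(np.sum(pred & ~labels)),
        fn=int(np.sum(~pred & labels)),
        tn=int(np.sum(~pred & ~labels)),
    )


def _as_labels(labels) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.dtype.kind in "SUO":
        lab = lab == "case"
    return lab.astype(bool)


def optimal_cutoff_by_mcc(scores, labels):
    """Scan midpoints between adjacent distinct scores for the MCC maximum.

    Returns (cutoff, ConfusionCounts, mcc).  Ties in MCC are broken toward
    higher specificity, then toward the higher cutoff.
    """
    s = np.asarray(scores, dtype=float)
    lab = _as_labels(labels)
    if lab.all() or not lab.any():
        raise ValueError("both classes must be present")
    distinct = np.unique(s)
    if len(distinct) < 2:
        raise ValueError("need at least two distinct scores")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate margins mid-scan
        for c in mids:
            cc = _confusion_at(s, lab, c)
            key = (mcc(cc), cc.specificity, c)
            if best is None or key > best[0]:
                best = (key, c, cc)
    _, cutoff, cc = best
    return float(cutoff), cc, mcc(cc)


def roc_curve(scores, labels) -> pd.DataFrame:
    """ROC points (1-specificity, sensitivity) over all distinct cutoffs."""
    s = np.asarray(scores, dtype=float)
    lab = _as_labels(labels)
    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    rows = []
    for t in thresholds:
        pred = s >= t
        tp = np.sum(pred & lab)
        fp = np.sum(pred & ~lab)
        rows.append({
            "threshold": t,
            "fpr": fp / max(np.sum(~lab), 1),
            "tpr": tp / max(np.sum(lab), 1),
        })
    return pd.DataFrame(rows)


def roc_auc(scores, labels) -> float:
    """AUC by the Mann-Whitney identity; ties count one half."""
    s = np.asarray(scores, dtype=float)
    lab = _as_labels(labels)
    if lab.all() or not lab.any():
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    n1 = int(lab.sum())
    n0 = len(s) - n1
    u = ranks[lab].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def clopper_pearson(successes: int, n: int, level: float = 0.95):
    """Exact binomial interval from beta quantiles; closed at 0 and 1."""
    if not (0 <= successes <= n) or n < 1:
        raise ValueError("require 0 <= successes <= n, n >= 1")
    a = (1.0 - level) / 2.0
    lo = 0.0 if successes == 0 else float(stats.beta.ppf(a, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(stats.beta.ppf(1 - a, successes + 1, n - successes))
    return lo, hi


def likelihood_ratios(counts: ConfusionCounts, level: float = 0.95):
    """LR+ = sens/(1-spec), LR- = (1-sens)/spec, with log-method CIs.

    Returns ((lr_plus, lo, hi), (lr_minus, lo, hi)).  A perfect specificity
    makes LR+ infinite with a one-sided interval.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    z = stats.norm.ppf(1 - (1 - level) / 2)
    sens, spec = counts.sensitivity, counts.specificity

    if spec == 1.0:
        lr_plus = (np.inf, np.nan, np.inf)
    else:
        lrp = sens / (1 - spec)
        se = np.sqrt(1 / tp - 1 / (tp + fn) + 1 / fp - 1 / (fp + tn))
        lr_plus = (lrp, lrp * np.exp(-z * se), lrp * np.exp(z * se))
    if spec == 0.0:
        lr_minus = (np.inf, np.nan, np.inf)
    else:
        lrm = (1 - sens) / spec
        se = np.sqrt(1 / fn - 1 / (tp + fn) + 1 / tn - 1 / (fp + tn))
        lr_minus = (lrm, lrm * np.exp(-z * se), lrm * np.exp(z * se))
    return lr_plus, lr_minus


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    Exact enumeration when the pooled sample has at most 20 values and no
    ties; otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    exact = len(pooled) <= 20 and len(np.unique(pooled)) == len(pooled)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class DiagnosticSummary:
    cutoff: float
    counts: ConfusionCounts
    mcc: float
    auc: float
    sensitivity: float
    sensitivity_ci: tuple
    specificity: float
    specificity_ci: tuple
    lr_plus: tuple
    lr_minus: tuple
    rank_test_p: float

    def to_frame(self) -> pd.DataFrame:
        c = self.counts
        return pd.DataFrame([{
            "cutoff": self.cutoff, "tp": c.tp, "fp": c.fp, "fn": c.fn,
            "tn": c.tn, "mcc": self.mcc, "auc": self.auc,
            "sensitivity": self.sensitivity,
            "sensitivity_lo": self.sensitivity_ci[0],
            "sensitivity_hi": self.sensitivity_ci[1],
            "specificity": self.specificity,
            "specificity_lo": self.specificity_ci[0],
            "specificity_hi": self.specificity_ci[1],
            "lr_plus": self.lr_plus[0], "lr_plus_lo": self.lr_plus[1],
            "lr_plus_hi": self.lr_plus[2],
            "lr_minus": self.lr_minus[0], "lr_minus_lo": self.lr_minus[1],
            "lr_minus_hi": self.lr_minus[2],
            "rank_test_p": self.rank_test_p,
        }])


def evaluate(scores, labels, level: float = 0.95) -> DiagnosticSummary:
    """Full evaluation of per-serum scores (duplicates already averaged)."""
    s = np.asarray(scores, dtype=float)
    lab = _as_labels(labels)
    cutoff, cc, best_mcc = optimal_cutoff_by_mcc(s, lab)
    lr_plus, lr_minus = likelihood_ratios(cc, level)
    _, p = rank_sum_test(s[lab], s[~lab])
    return DiagnosticSummary(
        cutoff=cutoff, counts=cc, mcc=best_mcc, auc=roc_auc(s, lab),
        sensitivity=cc.sensitivity,
        sensitivity_ci=clopper_pearson(cc.tp, cc.tp + cc.fn, level),
        specificity=cc.specificity,
        specificity_ci=clopper_pearson(cc.tn, cc.tn + cc.fp, level),
        lr_plus=lr_plus, lr_minus=lr_minus, rank_test_p=p,
    )
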