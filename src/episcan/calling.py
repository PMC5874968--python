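"""Epitope calls from posterior draws of the disease-binding profile.

A peptide is called an epitope when the Bayesian analogue of a p-value for
its disease effect falls below a threshold: p = 1 - alpha*, where alpha* is
the largest credibility mass whose highest-posterior-density (HPD) interval
still excludes zero.  With S retained draws the attainable values are
multiples of 1/S, so the smallest reportable p is 1/S — e.g. 0.000977 for
S = 1024.  Bonferroni multiplicity control over the peptide panel is
applied exactly (alpha/P); peptides can be annotated with membrane-topology
labels from a residue-interval file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tiling import PeptideTile


@dataclass(frozen=True)
class TopologyAnnotation:
    """Residue intervals (1-based inclusive) labelled by compartment."""

    intervals: tuple  # of (start, end, label)

    def __post_init__(self) -> None:
        for start, end, _ in self.intervals:
            if start < 1 or end < start:
                raise ValueError(f"bad interval ({start}, {end})")

    @classmethod
    def from_file(cls, path) -> "TopologyAnnotation":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["start", "end", "label"])
        return cls(tuple(df.itertuples(index=False, name=None)))

    def residue_labels(self, length: int) -> list[str | None]:
        labels: list[str | None] = [None] * length
        for start, end, label in self.intervals:
            for r in range(start, min(end, length) + 1):
                labels[r - 1] = label
        return labels

    def majority_label(self, start: int, end: int) -> str:
        """Majority compartment over a residue span; 'mixed' if no majority."""
        counts: dict[str, int] = {}
        for s, e, label in self.intervals:
            ov = min(e, end) - max(s, start) + 1
            if ov > 0:
                counts[label] = counts.get(label, 0) + ov
        if not counts:
            return "unknown"
        span = end - start + 1
        best = max(counts, key=counts.get)
        return best if counts[best] * 2 > span else "mixed"


def hpd_interval(draws, mass: float) -> tuple[float, float]:
    """Empirical HPD: shortest window of ceil(mass*S) order statistics.

    Ties in window width are broken toward the lowest start.  A degenerate
    sample yields a zero-width interval.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    S = len(x)
    if S < 10:
        raise ValueError("need at least 10 draws")
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must lie in (0, 1)")
    k = math.ceil(mass * S)
    widths = x[k - 1:] - x[:S - k + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum
    return float(x[i]), float(x[i + k - 1])


def p_bayes(draws) -> float:
    """1 minus the largest HPD mass whose interval excludes zero.

    The mass grid is {1/S, ..., 1}; if even the single-point interval
    contains zero the result is 1; the floor is 1/S.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    S = len(x)
    if S < 10:
        raise ValueError("need at least 10 draws")
    for k in range(S, 0, -1):
        widths = x[k - 1:] - x[:S - k + 1]
        i = int(np.argmin(widths))
        lo, hi = x[i], x[i + k - 1]
        if lo > 0.0 or hi < 0.0:
            return max(1.0 - k / S, 1.0 / S)
    return 1.0


def p_bayes_profile(f_s_draws: np.ndarray, legacy_1024: bool = False,
                    rng=None) -> np.ndarray:
    """p_bayes per peptide column of an (S, P) draw matrix.

    ``legacy_1024`` subsamples to 1024 draws, reproducing the p-value
    granularity of reports computed on 1024 posterior samples.
    """
    x = np.asarray(f_s_draws, dtype=float)
    if legacy_1024 and x.shape[0] > 1024:
        rng = np.random.default_rng(0) if rng is None else rng
        idx = rng.choice(x.shape[0], size=1024, replace=False)
        x = x[idx]
    return np.array([p_bayes(x[:, p]) for p in range(x.shape[1])])


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    return alpha / n_tests


def trunc_sigfigs(x: float, sig: int = 3) -> float:
    """Truncate toward zero at ``sig`` significant figures (display rule)."""
    if x == 0:
        return 0.0
    k = sig - 1 - math.floor(math.log10(abs(x)))
    return math.trunc(x * 10**k) / 10**k


def call_epitopes(
    summaries: pd.DataFrame,
    p_values,
    n_peptides: int,
    alpha: float = 0.05,
    topology: TopologyAnnotation | None = None,
    tiles: list[PeptideTile] | None = None,
) -> pd.DataFrame:
    """Flag significant peptides at nominal and Bonferroni thresholds.

    ``summaries`` is the per-peptide percent-increase table (indexed by
    peptide); direction comes from the sign of the posterior mean.  With a
    topology annotation and the tile list, each peptide gets the majority
    compartment of its residue span.
    """
    p = np.asarray(p_values, dtype=float)
    if len(p) != n_peptides or len(summaries) != n_peptides:
        raise ValueError("one p-value and one summary row per peptide required")
    calls = summaries.copy()
    calls["p_bayes"] = p
    calls["significant_nominal"] = p < alpha
    calls["significant_bonferroni"] = p < bonferroni_threshold(alpha, n_peptides)
    mean = calls["percent_increase_mean"].to_numpy()
    calls["direction"] = np.where(mean >= 0, "increased", "decreased")
    if topology is not None and tiles is not None:
        calls["topology"] = [
            topology.majority_label(t.start, t.end) for t in tiles
        ]
    return calls


def export_residue_scores(
    calls: pd.DataFrame,
    tiles: list[PeptideTile],
    topology: TopologyAnnotation | None = None,
) -> pd.DataFrame:
    """Per-residue mean percent-increase over all tiles covering the residue.

    The output has exactly one row per residue of the parent protein and is
    the numeric layer of a serpentine-style visualization.
    """
    L = max(t.end for t in tiles)
    total = np.zeros(L)
    count = np.zeros(L)
    for t in tiles:
        v = float(calls.loc[t.index, "percent_increase_mean"])
        total[t.start - 1:t.end] += v
        count[t.start - 1:t.end] += 1
    if (count == 0).any():
        raise ValueError("tiles do not cover every residue")
    out = pd.DataFrame({
        "residue": np.arange(1, L + 1),
        "percent_increase": total / count,
    })
    if topology is not None:
        out["topology"] = topology.residue_labels(L)
    return out
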