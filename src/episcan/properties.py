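"""Physicochemical descriptors of peptides.

Covers the quantities used as covariates and annotations in peptide-array
epitope mapping: Kyte-Doolittle mean hydropathy (GRAVY), Henderson-
Hasselbalch net charge and isoelectric point, average molecular weight
(with optional biotinylation), and Kolaskar-Tongaonkar antigenicity.

Charge and pI depend on the pKa constants assumed for the ionizable groups;
two widely used sets are shipped (``lehninger``, ``emboss``).  The default
is ``lehninger``, which reproduces reported peptide-array charge/pI columns
to within ~0.1 units in our hands; no single published set is canonical, so
the scale is always an explicit argument downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction

import numpy as np

from .tiling import PeptideTile, validate_sequence

# Kyte & Doolittle hydropathy, stored in tenths so means are exact rationals
_KD_TENTHS = {
    "A": 18, "R": -45, "N": -35, "D": -35, "C": 25, "Q": -35, "E": -35,
    "G": -4, "H": -32, "I": 45, "L": 38, "K": -39, "M": 19, "F": 28,
    "P": -16, "S": -8, "T": -7, "W": -9, "Y": -13, "V": 42,
}
KYTE_DOOLITTLE = {aa: v / 10.0 for aa, v in _KD_TENTHS.items()}

# average (isotope-abundance weighted) residue masses, Da
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153
BIOTINYL_MASS = 226.2954  # biotin (244.31) minus water lost on amide coupling

# pKa constant sets: termini plus the ionizable side chains
PKA_SCALES: dict[str, dict[str, float]] = {
    "lehninger": {
        "nterm": 9.69, "cterm": 2.34,
        "D": 3.65, "E": 4.25, "C": 8.33, "Y": 10.07,
        "K": 10.53, "R": 12.48, "H": 6.00,
    },
    "emboss": {
        "nterm": 8.6, "cterm": 3.6,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
        "K": 10.8, "R": 12.5, "H": 6.5,
    },
}
ACIDIC_GROUPS = ("cterm", "D", "E", "C", "Y")
BASIC_GROUPS = ("nterm", "K", "R", "H")

# Kolaskar & Tongaonkar antigenic propensity values
ANTIGENIC_PROPENSITY = {
    "A": 1.064, "R": 0.873, "N": 0.776, "D": 0.866, "C": 1.412,
    "Q": 1.015, "E": 0.851, "G": 0.874, "H": 1.105, "I": 1.152,
    "L": 1.250, "K": 0.930, "M": 0.826, "F": 1.091, "P": 1.064,
    "S": 1.012, "T": 0.909, "W": 0.893, "Y": 1.161, "V": 1.383,
}


@dataclass(frozen=True)
class PeptideProperties:
    """Descriptor bundle for one peptide."""

    length: int
    mw: float
    mw_biotinylated: float
    gravy: float
    charge: float
    pi: float


def round_half_away(x: float | Fraction, ndigits: int = 2) -> float:
    """Round with halves away from zero (the convention of most lab reports)."""
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        d = Decimal(repr(x))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    seq = validate_sequence(sequence)
    return sum(_KD_TENTHS[a] for a in seq) / (10.0 * len(seq))


def gravy_2dp(sequence: str) -> float:
    """GRAVY rounded to 2 decimals with exact half-away-from-zero arithmetic.

    The per-residue hydropathies are multiples of 0.1, so the mean is an
    exact rational; rounding it through floats would misplace .xx5 halves.
    """
    seq = validate_sequence(sequence)
    mean = Fraction(sum(_KD_TENTHS[a] for a in seq), 10 * len(seq))
    return round_half_away(mean, 2)


def _ionizable_counts(seq: str) -> dict[str, int]:
    counts = {g: 0 for g in PKA_SCALES["lehninger"]}
    counts["nterm"] = counts["cterm"] = 1
    for a in seq:
        if a in counts:
            counts[a] += 1
    return counts


def net_charge(sequence: str, pH: float = 7.0, pKa_scale: str = "lehninger") -> float:
    """Henderson-Hasselbalch net charge at ``pH`` in elementary charges.

    charge = sum over basic groups of 1/(1+10^(pH-pKa))
           - sum over acidic groups of 1/(1+10^(pKa-pH)).
    Monotone non-increasing in pH.
    """
    seq = validate_sequence(sequence)
    if not (0.0 < pH < 14.0):
        raise ValueError("pH must lie in (0, 14)")
    if pKa_scale not in PKA_SCALES:
        raise ValueError(
            f"unknown pKa scale {pKa_scale!r}; choose from {sorted(PKA_SCALES)}"
        )
    pka = PKA_SCALES[pKa_scale]
    counts = _ionizable_counts(seq)
    pos = sum(counts[g] / (1.0 + 10.0 ** (pH - pka[g])) for g in BASIC_GROUPS)
    neg = sum(counts[g] / (1.0 + 10.0 ** (pka[g] - pH)) for g in ACIDIC_GROUPS)
    return pos - neg


def isoelectric_point(
    sequence: str, pKa_scale: str = "lehninger", tol: float = 1e-4
) -> float:
    """pH at which the net charge vanishes, by bisection on (0, 14).

    Unique because the charge is monotone in pH and both termini are always
    present (charge is positive near pH 0 and negative near pH 14).
    """
    lo, hi = 1e-9, 14.0 - 1e-9
    c_lo = net_charge(sequence, lo, pKa_scale)
    c_hi = net_charge(sequence, hi, pKa_scale)
    if not (c_lo > 0 > c_hi):
        raise ValueError("net charge does not change sign on (0, 14)")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pKa_scale) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def molecular_weight(sequence: str, n_biotin: int = 0) -> float:
    """Average molecular weight in Da; ``n_biotin`` biotinyl groups added."""
    seq = validate_sequence(sequence)
    if n_biotin < 0:
        raise ValueError("n_biotin must be >= 0")
    return (
        sum(AVERAGE_RESIDUE_MASS[a] for a in seq)
        + WATER_MASS
        + n_biotin * BIOTINYL_MASS
    )


def peptide_properties(
    sequence: str,
    pH: float = 7.0,
    charge_scale: str = "lehninger",
    pi_scale: str = "emboss",
) -> PeptideProperties:
    """Descriptor bundle; note the per-column pKa defaults.

    Against reference peptide-array tables, Lehninger constants reproduce
    reported net charges best (within ~0.14 e) while EMBOSS constants
    reproduce reported pI values almost exactly (within 0.005 pH units), so
    the two columns default to different scales.  Pass the same scale to
    both arguments for a single-scale calculation.
    """
    seq = validate_sequence(sequence)
    return PeptideProperties(
        length=len(seq),
        mw=molecular_weight(seq),
        mw_biotinylated=molecular_weight(seq, n_biotin=1),
        gravy=gravy(seq),
        charge=net_charge(seq, pH, charge_scale),
        pi=isoelectric_point(seq, pi_scale),
    )


def properties_table(tiles: list[PeptideTile], pH: float = 7.0,
                     charge_scale: str = "lehninger", pi_scale: str = "emboss",
                     n_biotin: int = 1):
    """DataFrame of descriptors for a tile list, one row per peptide."""
    import pandas as pd

    rows = []
    for t in tiles:
        p = peptide_properties(t.sequence, pH, charge_scale, pi_scale)
        rows.append(
            {
                "peptide": t.index,
                "sequence": t.sequence,
                "length": p.length,
                "start": t.start,
                "end": t.end,
                "mw": p.mw + n_biotin * BIOTINYL_MASS,
                "gravy": gravy_2dp(t.sequence),
                "pi": round(p.pi, 2),
                "charge": round(p.charge, 2),
            }
        )
    return pd.DataFrame(rows).set_index("peptide")


def antigenicity_scores(sequence: str, window: int = 6) -> np.ndarray:
    """Per-residue antigenicity: mean of window propensity-means covering it."""
    seq = validate_sequence(sequence)
    L = len(seq)
    if L < window:
        raise ValueError("sequence shorter than window")
    prop = np.array([ANTIGENIC_PROPENSITY[a] for a in seq])
    kernel = np.ones(window) / window
    win_means = np.convolve(prop, kernel, mode="valid")  # length L-window+1
    scores = np.zeros(L)
    counts = np.zeros(L)
    for j, m in enumerate(win_means):
        scores[j:j + window] += m
        counts[j:j + window] += 1
    return scores / counts


def kolaskar_tongaonkar(
    sequence: str, window: int = 6, min_length: int = 6
) -> list[tuple[int, int, float]]:
    """Predict antigenic regions by sliding-window propensity averaging.

    Each window of ``window`` residues is scored by its mean antigenic
    propensity; a residue's score averages the windows covering it.
    Residues scoring above the whole-sequence mean window score are merged
    into maximal runs and runs shorter than ``min_length`` are dropped.
    Returns (start, end, mean score) with 1-based inclusive coordinates.
    """
    seq = validate_sequence(sequence)
    if len(seq) < window:
        import warnings

        warnings.warn("sequence shorter than window; no antigenic regions")
        return []
    prop = np.array([ANTIGENIC_PROPENSITY[a] for a in seq])
    win_means = np.convolve(prop, np.ones(window) / window, mode="valid")
    threshold = float(win_means.mean())
    scores = antigenicity_scores(seq, window)
    above = scores > threshold

    regions: list[tuple[int, int, float]] = []
    i = 0
    L = len(seq)
    while i < L:
        if above[i]:
            j = i
            while j + 1 < L and above[j + 1]:
                j += 1
            if j - i + 1 >= min_length:
                regions.append((i + 1, j + 1, float(scores[i:j + 1].mean())))
            i = j + 1
        else:
            i += 1
    return regions
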