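"""Synthetic plate-structured ELISA data with known ground truth.

The generator emulates the paired peptide-array design: one case serum and
one control serum per plate, every peptide in duplicate for each serum,
plus positive-control and blank wells.  The logit-scale signal of a well is
composed exactly as the signal-separation model assumes — intercept,
standardized pI and hydropathy effects, iid plate and serum effects, a
stationary AR(1) background profile shared by all sera, an AR(1) disease
profile entering case wells only (optionally overridden by explicit epitope
"bumps"), and Gaussian noise — then mapped through the inverse logit and an
affine rescale into an OD450 range.  Because per-plate min/max
re-normalization is re-estimated downstream, the pipeline inverts this map
only approximately, mirroring what happens with real plates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import cxcr3
from .elisa import PlateTable


@dataclass
class SyntheticConfig:
    """Study conditions; defaults mirror a 30-pair, 36-peptide array."""

    n_pairs: int = 30
    n_peptides: int = 36
    replicates: int = 2
    beta0: float = -1.2
    beta_pi: float = 0.15
    beta_hyd: float = -0.25
    sigma_plate: float = 0.3
    sigma_serum: float = 0.4
    sigma_eps: float = 0.4
    rho_bg: float = 0.6
    sigma_bg: float = 0.6
    rho_s: float = 0.6
    sigma_s: float = 0.3
    epitope_spec: tuple = ()   # ((start_pep, end_pep, height_logit), ...)
    od_range: tuple = (0.05, 3.5)
    seed: int = 0
    peptide_properties: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if min(self.sigma_plate, self.sigma_serum, self.sigma_eps,
               self.sigma_bg, self.sigma_s) < 0:
            raise ValueError("standard deviations must be >= 0")
        for rho in (self.rho_bg, self.rho_s):
            if not (-1.0 < rho < 1.0):
                raise ValueError("AR(1) correlations must lie in (-1, 1)")
        lo, hi = self.od_range
        if not (0.0 < lo < hi):
            raise ValueError("od_range must satisfy 0 < lo < hi")


@dataclass
class SyntheticDataset:
    plate_table: PlateTable
    truth: dict


def _ar1_path(P: int, rho: float, sigma: float, rng) -> np.ndarray:
    """Stationary AR(1) with marginal sd ``sigma``."""
    f = np.empty(P)
    f[0] = rng.standard_normal() * sigma
    innov_sd = sigma * np.sqrt(1.0 - rho**2)
    for t in range(1, P):
        f[t] = rho * f[t - 1] + innov_sd * rng.standard_normal()
    return f


def _well_names(n: int) -> list[str]:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWX"
    return [f"{letters[i // 12]}{i % 12 + 1:02d}" for i in range(n)]


def _standardized_covariates(cfg: SyntheticConfig):
    props = cfg.peptide_properties
    if props is None:
        props = cxcr3.peptide_properties_frame()
    if cfg.n_peptides > len(props):
        raise ValueError("n_peptides exceeds available peptide properties")
    pi = props["pi"].to_numpy(dtype=float)[:cfg.n_peptides]
    hyd = props["gravy"].to_numpy(dtype=float)[:cfg.n_peptides]
    z = lambda v: (v - v.mean()) / v.std(ddof=0)
    return z(pi), z(hyd)


def true_disease_profile(cfg: SyntheticConfig, rng=None) -> np.ndarray:
    """AR(1) draw scaled by sigma_s, overlaid with epitope bumps."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    f_s = _ar1_path(cfg.n_peptides, cfg.rho_s, cfg.sigma_s, rng)
    for start, end, height in cfg.epitope_spec:
        f_s[start - 1:end] += height
    return f_s


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """One plate per serum pair; fully reproducible from ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    P = cfg.n_peptides
    lo, hi = cfg.od_range

    pi_std, hyd_std = _standardized_covariates(cfg)
    f_bg = _ar1_path(P, cfg.rho_bg, cfg.sigma_bg, rng)
    f_s = true_disease_profile(cfg, rng)

    plate_eff = rng.standard_normal(cfg.n_pairs) * cfg.sigma_plate
    serum_eff = rng.standard_normal(2 * cfg.n_pairs) * cfg.sigma_serum

    rows = []
    for k in range(cfg.n_pairs):
        plate = f"plate{k + 1:03d}"
        sera = [(f"case{k + 1:03d}", "case", serum_eff[2 * k]),
                (f"ctrl{k + 1:03d}", "control", serum_eff[2 * k + 1])]
        wells = iter(_well_names(2 * (P + 2) * cfg.replicates))
        for serum_id, group, b in sera:
            w = 1.0 if group == "case" else 0.0
            for rep in range(1, cfg.replicates + 1):
                for p in range(P):
                    eta = (cfg.beta0 + cfg.beta_pi * pi_std[p]
                           + cfg.beta_hyd * hyd_std[p] + plate_eff[k] + b
                           + f_bg[p] + w * f_s[p]
                           + cfg.sigma_eps * rng.standard_normal())
                    od = lo + (hi - lo) / (1.0 + np.exp(-eta))
                    rows.append((plate, next(wells), "peptide", p + 1,
                                 serum_id, group, rep, od))
                od_pos = np.clip(0.9 * hi + 0.03 * rng.standard_normal(),
                                 lo * 1.01, hi * 0.999)
                rows.append((plate, next(wells), "positive_control", None,
                             serum_id, group, rep, od_pos))
                od_blank = lo * (1.0 + 0.2 * abs(rng.standard_normal()))
                rows.append((plate, next(wells), "blank", None,
                             serum_id, group, rep, min(od_blank, hi * 0.999)))
    df = pd.DataFrame(rows, columns=[
        "plate_id", "well", "role", "peptide", "serum_id", "group",
        "replicate", "od450",
    ])
    truth = {
        "f_bg": f_bg, "f_s": f_s,
        "plate_effects": plate_eff, "serum_effects": serum_eff,
        "config": cfg,
    }
    return SyntheticDataset(plate_table=PlateTable(df), truth=truth)


# the three canonical intracellular bump regions used by the fixture suite
BUMP_REGIONS = ((16, 17), (24, 25), (33, 34))


def make_null_and_alternative_suite(
    seed: int, n_pairs: int = 30, replicates: int = 2
) -> dict[str, SyntheticDataset]:
    """Canonical fixture trio sharing design dimensions.

    ``null`` has no disease signal at all; ``weak`` and ``strong`` place
    deterministic bumps (+0.5 and +1.5 logit units) on the three
    intracellular epitope regions, with no disease signal elsewhere.
    """
    base = SyntheticConfig(n_pairs=n_pairs, replicates=replicates, sigma_s=0.0)
    ss = np.random.SeedSequence(seed).generate_state(3)
    out = {}
    for name, height, sub_seed in (
        ("null", 0.0, ss[0]), ("weak", 0.5, ss[1]), ("strong", 1.5, ss[2])
    ):
        spec = () if height == 0.0 else tuple(
            (a, b, height) for a, b in BUMP_REGIONS
        )
        cfg = replace(base, epitope_spec=spec, seed=int(sub_seed % 2**31))
        out[name] = generate(cfg)
    return out


def write_truth(dataset: SyntheticDataset, path) -> None:
    """Persist the latent truth as a tidy TSV (parameter, index, value)."""
    t = dataset.truth
    rows = []
    for name in ("f_bg", "f_s", "plate_effects", "serum_effects"):
        for i, v in enumerate(t[name], start=1):
            rows.append((name, i, v))
    cfg = t["config"]
    for fld in ("beta0", "beta_pi", "beta_hyd", "sigma_plate", "sigma_serum",
                "sigma_eps", "rho_bg", "sigma_bg", "rho_s", "sigma_s"):
        rows.append((fld, 1, getattr(cfg, fld)))
    pd.DataFrame(rows, columns=["parameter", "index", "value"]).to_csv(
        path, sep="\t", index=False
    )
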