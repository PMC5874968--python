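"""Bayesian signal separation for peptide-array ELISA data.

The logit-scale reading of well *i* (serum s(i), plate k(i), peptide p(i))
is modeled as

    y_i = b0 + b_pI * pI_{p(i)} + b_hyd * hyd_{p(i)}
          + a_{k(i)} + u_{s(i)} + f_bg[p(i)] + w_i * f_s[p(i)] + eps_i

with iid Gaussian plate and serum effects, iid noise, and two latent
peptide-indexed profiles: a background profile f_bg shared by everyone and
a disease profile f_s that enters only case observations (w_i = 1 for case
sera, 0 for controls).  Both profiles are stationary AR(1) Gaussian
processes over the peptide index, encoding that overlapping neighbouring
peptides should bind similarly; the weighting isolates the case-specific
component of binding from everything sera have in common.

Inference is a blocked Gibbs sampler: every Gaussian block (fixed effects,
plate/serum effects, both AR(1) profiles) is drawn from its exact full
conditional; the AR(1) correlations use random-walk Metropolis on
atanh(rho); standard deviations carry half-Cauchy priors implemented by the
inverse-gamma auxiliary-variable expansion, so their updates are conjugate
too.  The background profile is constrained to sum to zero (conditioning by
kriging) to keep the intercept identifiable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ModelInputs:
    """Design arrays for the sampler; observations sorted canonically."""

    y: np.ndarray
    pi: np.ndarray            # standardized peptide pI per observation
    hyd: np.ndarray           # standardized peptide hydropathy per observation
    plate_idx: np.ndarray     # 0-based
    serum_idx: np.ndarray
    pep_idx: np.ndarray
    w: np.ndarray             # 1 for case sera, 0 for controls
    n_plates: int
    n_sera: int
    n_peptides: int
    plate_levels: list = field(default_factory=list)
    serum_levels: list = field(default_factory=list)
    standardization: dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return len(self.y)


@dataclass
class ModelConfig:
    """Sampler settings and priors; the defaults are deliberately vague."""

    n_chains: int = 4
    n_iterations: int = 5000
    n_burnin: int = 2500
    thinning: int = 2
    seed: int = 0
    fixed_effect_variance: float = 1000.0
    half_cauchy_scale: float = 1.0
    rw_step: float = 0.4            # random-walk sd on atanh(rho)
    # fixing hooks (used for oracle checks and degenerate designs)
    fix_rho_bg: float | None = None
    fix_rho_s: float | None = None
    fix_sigma2: dict | None = None  # keys among plate/serum/eps/bg/s

    def __post_init__(self) -> None:
        if not (self.n_iterations > self.n_burnin >= 0):
            raise ValueError("require n_iterations > n_burnin >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class PosteriorDraws:
    """Retained posterior draws, concatenated across chains."""

    beta: np.ndarray       # (S, 3): intercept, b_pI, b_hyd
    sigma2_plate: np.ndarray
    sigma2_serum: np.ndarray
    sigma2_eps: np.ndarray
    sigma2_bg: np.ndarray
    sigma2_s: np.ndarray
    rho_bg: np.ndarray
    rho_s: np.ndarray
    f_bg: np.ndarray       # (S, P)
    f_s: np.ndarray        # (S, P)
    chain: np.ndarray      # chain id per draw
    warnings: list = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return len(self.sigma2_eps)

    @property
    def n_peptides(self) -> int:
        return self.f_s.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        cols = {
            "chain": self.chain,
            "beta0": self.beta[:, 0],
            "beta_pi": self.beta[:, 1],
            "beta_hyd": self.beta[:, 2],
            "sigma2_plate": self.sigma2_plate,
            "sigma2_serum": self.sigma2_serum,
            "sigma2_eps": self.sigma2_eps,
            "sigma2_bg": self.sigma2_bg,
            "sigma2_s": self.sigma2_s,
            "rho_bg": self.rho_bg,
            "rho_s": self.rho_s,
        }
        for p in range(self.n_peptides):
            cols[f"f_bg_{p + 1}"] = self.f_bg[:, p]
            cols[f"f_s_{p + 1}"] = self.f_s[:, p]
        return pd.DataFrame(cols)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PosteriorDraws":
        P = sum(c.startswith("f_s_") for c in df.columns)
        return cls(
            beta=df[["beta0", "beta_pi", "beta_hyd"]].to_numpy(),
            sigma2_plate=df["sigma2_plate"].to_numpy(),
            sigma2_serum=df["sigma2_serum"].to_numpy(),
            sigma2_eps=df["sigma2_eps"].to_numpy(),
            sigma2_bg=df["sigma2_bg"].to_numpy(),
            sigma2_s=df["sigma2_s"].to_numpy(),
            rho_bg=df["rho_bg"].to_numpy(),
            rho_s=df["rho_s"].to_numpy(),
            f_bg=df[[f"f_bg_{p + 1}" for p in range(P)]].to_numpy(),
            f_s=df[[f"f_s_{p + 1}" for p in range(P)]].to_numpy(),
            chain=df["chain"].to_numpy(),
        )


def build_inputs(normalized: pd.DataFrame, properties: pd.DataFrame) -> ModelInputs:
    """Assemble sampler inputs from preprocessed readings and peptide props.

    ``properties`` must be indexed by peptide and provide ``pi`` and
    ``gravy`` columns; covariates are centered and scaled over the peptide
    panel, and the constants are recorded for back-transformation.
    Observations are sorted canonically so results do not depend on input
    row order.
    """
    df = normalized.sort_values(
        ["plate_id", "serum_id", "peptide", "replicate"]
    ).reset_index(drop=True)
    peptides = np.sort(df["peptide"].unique())
    missing = [int(p) for p in peptides if p not in properties.index]
    if missing:
        raise ValueError(f"missing peptide properties for {missing}")
    P = int(peptides.max())
    if set(peptides) != set(range(1, P + 1)):
        raise ValueError("peptide indices must be contiguous 1..P")

    pi_raw = properties.loc[range(1, P + 1), "pi"].to_numpy(dtype=float)
    hyd_raw = properties.loc[range(1, P + 1), "gravy"].to_numpy(dtype=float)
    std = {
        "pi_mean": pi_raw.mean(), "pi_sd": pi_raw.std(ddof=0),
        "hyd_mean": hyd_raw.mean(), "hyd_sd": hyd_raw.std(ddof=0),
    }
    pi_std = (pi_raw - std["pi_mean"]) / std["pi_sd"]
    hyd_std = (hyd_raw - std["hyd_mean"]) / std["hyd_sd"]

    plate_levels = list(dict.fromkeys(df["plate_id"]))
    serum_levels = list(dict.fromkeys(df["serum_id"]))
    plate_idx = df["plate_id"].map({p: i for i, p in enumerate(plate_levels)})
    serum_idx = df["serum_id"].map({s: i for i, s in enumerate(serum_levels)})
    pep_idx = df["peptide"].astype(int).to_numpy() - 1
    w = (df["group"] == "case").to_numpy(dtype=float)

    return ModelInputs(
        y=df["y"].to_numpy(dtype=float),
        pi=pi_std[pep_idx],
        hyd=hyd_std[pep_idx],
        plate_idx=plate_idx.to_numpy(dtype=int),
        serum_idx=serum_idx.to_numpy(dtype=int),
        pep_idx=pep_idx,
        w=w,
        n_plates=len(plate_levels),
        n_sera=len(serum_levels),
        n_peptides=P,
        plate_levels=plate_levels,
        serum_levels=serum_levels,
        standardization=std,
    )


def ar1_precision(P: int, rho: float, sigma2: float) -> np.ndarray:
    """Precision of a stationary AR(1) with marginal variance sigma2."""
    B = np.zeros((P, P))
    idx = np.arange(P)
    B[idx, idx] = 1.0 + rho**2
    B[0, 0] = B[-1, -1] = 1.0
    B[idx[:-1], idx[1:]] = -rho
    B[idx[1:], idx[:-1]] = -rho
    return B / (sigma2 * (1.0 - rho**2))


def _ar1_quad(f: np.ndarray, rho: float) -> float:
    """f' R(rho)^{-1} f for the unit-variance stationary AR(1) correlation."""
    s0 = float(f @ f)
    s0m = float(f[1:-1] @ f[1:-1]) if len(f) > 2 else 0.0
    s1 = float(f[:-1] @ f[1:])
    return (s0 + rho**2 * s0m - 2.0 * rho * s1) / (1.0 - rho**2)


def _sample_gaussian(prec: np.ndarray, lin: np.ndarray, rng) -> np.ndarray:
    """Draw from N(prec^{-1} lin, prec^{-1}) via Cholesky."""
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, lin)
    z = rng.standard_normal(len(lin))
    return mean + np.linalg.solve(L.T, z)


def _sample_gaussian_sum_zero(prec: np.ndarray, lin: np.ndarray, rng) -> np.ndarray:
    """Draw from the Gaussian above conditioned on sum(x) = 0 (kriging)."""
    x = _sample_gaussian(prec, lin, rng)
    v = np.linalg.solve(prec, np.ones(len(lin)))  # Sigma @ 1
    return x - v * (x.sum() / v.sum())


def _draw_inv_gamma(shape: float, rate: float, rng) -> float:
    return rate / rng.gamma(shape)


def split_rhat(x: np.ndarray, chain: np.ndarray) -> float:
    """Split-R-hat of a scalar chain collection (Gelman et al.)."""
    halves = []
    for c in np.unique(chain):
        xs = x[chain == c]
        h = len(xs) // 2
        if h < 2:
            return np.nan
        halves.extend([xs[:h], xs[h:2 * h]])
    m = len(halves)
    n = len(halves[0])
    means = np.array([h.mean() for h in halves])
    vars_ = np.array([h.var(ddof=1) for h in halves])
    W = vars_.mean()
    B = n * means.var(ddof=1)
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W)) if W > 0 else np.nan


def fit_model(inputs: ModelInputs, config: ModelConfig) -> PosteriorDraws:
    """Run the blocked Gibbs sampler; seed-deterministic.

    Rejects designs with only one serum group (the disease profile would be
    unidentifiable).  Emits a convergence warning (also recorded on the
    result) when the split-R-hat of any disease-profile component exceeds
    1.1.
    """
    if inputs.w.min() == inputs.w.max():
        raise ValueError("need both case and control sera: f_s is "
                         "unidentifiable from a single group")
    if inputs.n_peptides < 2:
        raise ValueError("need at least 2 peptides")

    master = np.random.SeedSequence(config.seed)
    chains = [
        _run_chain(inputs, config, np.random.default_rng(s), c)
        for c, s in enumerate(master.spawn(config.n_chains))
    ]
    out = {
        k: np.concatenate([ch[k] for ch in chains])
        for k in chains[0]
    }
    draws = PosteriorDraws(
        beta=out["beta"], sigma2_plate=out["sigma2_plate"],
        sigma2_serum=out["sigma2_serum"], sigma2_eps=out["sigma2_eps"],
        sigma2_bg=out["sigma2_bg"], sigma2_s=out["sigma2_s"],
        rho_bg=out["rho_bg"], rho_s=out["rho_s"],
        f_bg=out["f_bg"], f_s=out["f_s"], chain=out["chain"],
    )
    if config.n_chains >= 2:
        rhats = [
            split_rhat(draws.f_s[:, p], draws.chain)
            for p in range(inputs.n_peptides)
        ]
        worst = np.nanmax(rhats)
        if worst > 1.1:
            msg = (f"possible non-convergence: max split-R-hat on the disease "
                   f"profile is {worst:.3f} (> 1.1)")
            warnings.warn(msg)
            draws.warnings.append(msg)
    return draws


def _run_chain(inputs: ModelInputs, cfg: ModelConfig, rng, chain_id: int) -> dict:
    y = inputs.y
    n = inputs.n_obs
    P = inputs.n_peptides
    X = np.column_stack([np.ones(n), inputs.pi, inputs.hyd])
    XtX = X.T @ X
    plate_idx, serum_idx, pep_idx, w = (
        inputs.plate_idx, inputs.serum_idx, inputs.pep_idx, inputs.w,
    )
    case = w == 1.0
    n_plate = np.bincount(plate_idx, minlength=inputs.n_plates)
    n_serum = np.bincount(serum_idx, minlength=inputs.n_sera)
    n_pep = np.bincount(pep_idx, minlength=P).astype(float)
    n_pep_case = np.bincount(pep_idx[case], minlength=P).astype(float)
    pep_idx_case = pep_idx[case]

    fixed = cfg.fix_sigma2 or {}
    A2 = cfg.half_cauchy_scale**2

    # initial state
    beta = np.zeros(3)
    beta[0] = y.mean()
    a = np.zeros(inputs.n_plates)
    b = np.zeros(inputs.n_sera)
    f_bg = np.zeros(P)
    f_s = np.zeros(P)
    sig2 = {"plate": 0.1, "serum": 0.1, "eps": max(y.var(), 1e-3),
            "bg": 0.1, "s": 0.1}
    sig2.update(fixed)
    aux = {k: 1.0 for k in sig2}
    rho_bg = cfg.fix_rho_bg if cfg.fix_rho_bg is not None else 0.0
    rho_s = cfg.fix_rho_s if cfg.fix_rho_s is not None else 0.0

    keep = (cfg.n_iterations - cfg.n_burnin) // cfg.thinning
    store = {
        "beta": np.empty((keep, 3)), "f_bg": np.empty((keep, P)),
        "f_s": np.empty((keep, P)),
        **{k: np.empty(keep) for k in (
            "sigma2_plate", "sigma2_serum", "sigma2_eps", "sigma2_bg",
            "sigma2_s", "rho_bg", "rho_s")},
    }
    kept = 0

    def var_update(name: str, quad: float, m: int) -> float:
        # sigma2 ~ IG(1/2, 1/aux), aux ~ IG(1/2, 1/A^2): half-Cauchy(A) on sigma
        if name in fixed:
            return sig2[name]
        s2 = _draw_inv_gamma((m + 1) / 2.0, quad / 2.0 + 1.0 / aux[name], rng)
        aux[name] = _draw_inv_gamma(1.0, 1.0 / s2 + 1.0 / A2, rng)
        return s2

    def rho_update(rho: float, f: np.ndarray, s2: float, fixed_rho) -> float:
        if fixed_rho is not None:
            return rho
        z = np.arctanh(rho)

        def logpost(zz: float) -> float:
            r = np.tanh(zz)
            return (
                -0.5 * (P - 1) * np.log1p(-r**2)
                - _ar1_quad(f, r) / (2.0 * s2)
                + np.log1p(-r**2)  # Jacobian of tanh
            )

        z_new = z + cfg.rw_step * rng.standard_normal()
        if np.log(rng.uniform()) < logpost(z_new) - logpost(z):
            return float(np.tanh(z_new))
        return rho

    for it in range(cfg.n_iterations):
        rand_part = a[plate_idx] + b[serum_idx] + f_bg[pep_idx] + w * f_s[pep_idx]

        # fixed effects
        r = y - rand_part
        prec = XtX / sig2["eps"] + np.eye(3) / cfg.fixed_effect_variance
        beta = _sample_gaussian(prec, X.T @ r / sig2["eps"], rng)
        fix_part = X @ beta

        # plate effects
        r = y - fix_part - b[serum_idx] - f_bg[pep_idx] - w * f_s[pep_idx]
        s = np.bincount(plate_idx, weights=r, minlength=inputs.n_plates)
        prec_a = n_plate / sig2["eps"] + 1.0 / sig2["plate"]
        a = s / sig2["eps"] / prec_a + rng.standard_normal(inputs.n_plates) / np.sqrt(prec_a)

        # serum effects
        r = y - fix_part - a[plate_idx] - f_bg[pep_idx] - w * f_s[pep_idx]
        s = np.bincount(serum_idx, weights=r, minlength=inputs.n_sera)
        prec_b = n_serum / sig2["eps"] + 1.0 / sig2["serum"]
        b = s / sig2["eps"] / prec_b + rng.standard_normal(inputs.n_sera) / np.sqrt(prec_b)

        # background profile, sum-to-zero constrained
        r = y - fix_part - a[plate_idx] - b[serum_idx] - w * f_s[pep_idx]
        s = np.bincount(pep_idx, weights=r, minlength=P)
        Q = ar1_precision(P, rho_bg, sig2["bg"]) + np.diag(n_pep / sig2["eps"])
        f_bg = _sample_gaussian_sum_zero(Q, s / sig2["eps"], rng)

        # disease profile (case observations only)
        r = (y - fix_part - a[plate_idx] - b[serum_idx] - f_bg[pep_idx])[case]
        s = np.bincount(pep_idx_case, weights=r, minlength=P)
        Q = ar1_precision(P, rho_s, sig2["s"]) + np.diag(n_pep_case / sig2["eps"])
        f_s = _sample_gaussian(Q, s / sig2["eps"], rng)

        # variance components
        resid = y - fix_part - a[plate_idx] - b[serum_idx] \
            - f_bg[pep_idx] - w * f_s[pep_idx]
        sig2["eps"] = var_update("eps", float(resid @ resid), n)
        sig2["plate"] = var_update("plate", float(a @ a), inputs.n_plates)
        sig2["serum"] = var_update("serum", float(b @ b), inputs.n_sera)
        sig2["bg"] = var_update("bg", _ar1_quad(f_bg, rho_bg), P)
        sig2["s"] = var_update("s", _ar1_quad(f_s, rho_s), P)

        # AR(1) correlations
        rho_bg = rho_update(rho_bg, f_bg, sig2["bg"], cfg.fix_rho_bg)
        rho_s = rho_update(rho_s, f_s, sig2["s"], cfg.fix_rho_s)

        if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thinning == 0 \
                and kept < keep:
            store["beta"][kept] = beta
            store["f_bg"][kept] = f_bg
            store["f_s"][kept] = f_s
            store["sigma2_plate"][kept] = sig2["plate"]
            store["sigma2_serum"][kept] = sig2["serum"]
            store["sigma2_eps"][kept] = sig2["eps"]
            store["sigma2_bg"][kept] = sig2["bg"]
            store["sigma2_s"][kept] = sig2["s"]
            store["rho_bg"][kept] = rho_bg
            store["rho_s"][kept] = rho_s
            kept += 1

    store["chain"] = np.full(keep, chain_id)
    return store


def percent_increase(draws: PosteriorDraws,
                     masses: tuple[float, ...] = (0.95, 0.999)) -> pd.DataFrame:
    """Per-peptide disease-signal summary on the percent scale.

    The logit-scale disease effect f_s[p] is mapped per draw to the
    odds-scale fold change 100*(exp(f_s)-1), then summarized by the
    posterior mean plus equal-tailed and highest-posterior-density bands.
    """
    from .calling import hpd_interval

    pct = 100.0 * np.expm1(draws.f_s)
    rows = []
    for p in range(draws.n_peptides):
        x = pct[:, p]
        row = {"peptide": p + 1, "percent_increase_mean": float(x.mean())}
        for m in masses:
            tag = f"{m * 100:g}"
            lo, hi = np.quantile(x, [(1 - m) / 2, (1 + m) / 2])
            row[f"eti{tag}_lo"], row[f"eti{tag}_hi"] = float(lo), float(hi)
            h_lo, h_hi = hpd_interval(x, m)
            row[f"hpd{tag}_lo"], row[f"hpd{tag}_hi"] = h_lo, h_hi
        rows.append(row)
    return pd.DataFrame(rows).set_index("peptide")
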