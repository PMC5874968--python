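import warnings

import numpy as np
import pandas as pd
import pytest

from episcan import model
from episcan.model import ModelConfig, PosteriorDraws, ar1_precision, build_inputs

from conftest import direct_model_dataset


def _quiet_fit(inputs, cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit_model(inputs, cfg)


def test_build_inputs_bookkeeping(small_normalized, peptide_props):
    inp = build_inputs(small_normalized, peptide_props)
    # some serum runs were removed by QC; levels mirror what survived
    assert inp.n_plates == small_normalized["plate_id"].nunique()
    assert inp.n_sera == small_normalized["serum_id"].nunique()
    assert inp.n_peptides == 36
    assert inp.n_obs == len(small_normalized)
    # weight vector mirrors the group column exactly
    expected_w = (
        small_normalized.sort_values(
            ["plate_id", "serum_id", "peptide", "replicate"]
        )["group"] == "case"
    ).to_numpy(dtype=float)
    assert np.array_equal(inp.w, expected_w)
    # standardized covariates over the peptide panel
    for cov in (inp.pi, inp.hyd):
        by_pep = pd.Series(cov).groupby(inp.pep_idx).first()
        assert by_pep.mean() == pytest.approx(0, abs=1e-10)
        assert by_pep.std(ddof=0) == pytest.approx(1, abs=1e-10)


def test_build_inputs_rejects_missing_properties(small_normalized, peptide_props):
    with pytest.raises(ValueError, match="missing peptide"):
        build_inputs(small_normalized, peptide_props.drop(index=5))


def test_fit_rejects_single_group(small_normalized, peptide_props):
    cases = small_normalized[small_normalized["group"] == "case"]
    inp = build_inputs(cases, peptide_props)
    with pytest.raises(ValueError, match="unidentifiable"):
        model.fit_model(inp, ModelConfig(n_iterations=10, n_burnin=0))


def test_ar1_precision_inverts_the_ar1_covariance():
    P, rho, s2 = 7, 0.55, 1.7
    cov = s2 * rho ** np.abs(np.subtract.outer(np.arange(P), np.arange(P)))
    assert ar1_precision(P, rho, s2) @ cov == pytest.approx(np.eye(P), abs=1e-10)


def test_seed_determinism_and_draw_count(small_normalized, peptide_props):
    inp = build_inputs(small_normalized, peptide_props)
    cfg = ModelConfig(n_chains=2, n_iterations=80, n_burnin=40, thinning=2, seed=9)
    d1 = _quiet_fit(inp, cfg)
    d2 = _quiet_fit(inp, cfg)
    assert d1.n_draws == 2 * (80 - 40) // 2
    assert np.array_equal(d1.f_s, d2.f_s)
    assert np.array_equal(d1.beta, d2.beta)
    assert (np.abs(d1.rho_bg) < 1).all() and (np.abs(d1.rho_s) < 1).all()
    assert (d1.sigma2_eps > 0).all()


def test_observation_order_does_not_matter(small_normalized, peptide_props):
    cfg = ModelConfig(n_chains=1, n_iterations=60, n_burnin=20, thinning=1, seed=3)
    d1 = _quiet_fit(build_inputs(small_normalized, peptide_props), cfg)
    shuffled = small_normalized.sample(frac=1.0, random_state=11)
    d2 = _quiet_fit(build_inputs(shuffled, peptide_props), cfg)
    assert np.array_equal(d1.f_s, d2.f_s)


def test_posterior_draws_roundtrip(small_normalized, peptide_props):
    inp = build_inputs(small_normalized, peptide_props)
    cfg = ModelConfig(n_chains=1, n_iterations=40, n_burnin=20, thinning=1, seed=1)
    d = _quiet_fit(inp, cfg)
    back = PosteriorDraws.from_dataframe(d.to_dataframe())
    assert np.array_equal(back.f_bg, d.f_bg)
    assert np.array_equal(back.rho_s, d.rho_s)


def test_null_disease_profile_is_recovered_as_zero(peptide_props):
    """With no disease signal, f_s posteriors concentrate near zero."""
    rng = np.random.default_rng(77)
    df, props, fs_true = direct_model_dataset(rng, n_pairs=8, n_peptides=12,
                                              sigma_s=0.0)
    assert np.allclose(fs_true, 0)
    inp = build_inputs(df, props)
    d = _quiet_fit(inp, ModelConfig(n_chains=2, n_iterations=1500,
                                    n_burnin=500, thinning=1, seed=5))
    mean = d.f_s.mean(axis=0)
    sd = d.f_s.std(axis=0)
    frac_within = np.mean(np.abs(mean) <= 2 * sd)
    assert frac_within >= 0.9


def test_shift_conservation(peptide_props):
    """Adding c to every reading shifts the intercept, not the disease profile."""
    rng = np.random.default_rng(123)
    df, props, _ = direct_model_dataset(rng, n_pairs=6, n_peptides=10)
    cfg = ModelConfig(n_chains=2, n_iterations=1500, n_burnin=500, thinning=1,
                      seed=21)
    d0 = _quiet_fit(build_inputs(df, props), cfg)
    shifted = df.assign(y=df["y"] + 5.0)
    d1 = _quiet_fit(build_inputs(shifted, props), cfg)

    def mcse(x):
        return x.std() / np.sqrt(len(x) / 10.0)  # crude ESS deflation

    assert d1.beta[:, 0].mean() - d0.beta[:, 0].mean() == pytest.approx(
        5.0, abs=3 * (mcse(d0.beta[:, 0]) + mcse(d1.beta[:, 0])) + 0.05
    )
    diff = d1.f_s.mean(0) - d0.f_s.mean(0)
    tol = 3 * (d0.f_s.std(0) + d1.f_s.std(0)) / np.sqrt(d0.n_draws / 10.0)
    assert np.all(np.abs(diff) <= tol + 0.05)


def test_credible_interval_calibration():
    """95% intervals for f_s cover the truth at the nominal rate (+-5 pts)."""
    hits = tot = 0
    for rep in range(200):
        rng = np.random.default_rng(70_000 + rep)
        df, props, fs_true = direct_model_dataset(rng)
        inp = build_inputs(df, props)
        cfg = ModelConfig(n_chains=1, n_iterations=1000, n_burnin=400,
                          thinning=1, seed=rep)
        d = _quiet_fit(inp, cfg)
        lo, hi = np.quantile(d.f_s, [0.025, 0.975], axis=0)
        hits += int(np.sum((fs_true >= lo) & (fs_true <= hi)))
        tot += len(fs_true)
    assert 0.90 <= hits / tot <= 1.0


def test_percent_increase_closed_forms():
    S, P = 200, 3
    f_s = np.zeros((S, P))
    f_s[:, 1] = np.log(1.5)
    f_s[:, 2] = np.linspace(-1, 1, S)
    d = PosteriorDraws(
        beta=np.zeros((S, 3)), sigma2_plate=np.ones(S), sigma2_serum=np.ones(S),
        sigma2_eps=np.ones(S), sigma2_bg=np.ones(S), sigma2_s=np.ones(S),
        rho_bg=np.zeros(S), rho_s=np.zeros(S), f_bg=np.zeros((S, P)),
        f_s=f_s, chain=np.zeros(S),
    )
    out = model.percent_increase(d)
    assert out.loc[1, "percent_increase_mean"] == 0.0
    assert out.loc[2, "percent_increase_mean"] == pytest.approx(50.0)
    # bands nest: the 99.9% band contains the 95% band
    assert out.loc[3, "eti99.9_lo"] <= out.loc[3, "eti95_lo"]
    assert out.loc[3, "eti99.9_hi"] >= out.loc[3, "eti95_hi"]
    assert out.loc[3, "hpd99.9_hi"] - out.loc[3, "hpd99.9_lo"] >= (
        out.loc[3, "hpd95_hi"] - out.loc[3, "hpd95_lo"]
    )
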