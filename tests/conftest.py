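import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from episcan import cxcr3, elisa, simulate, tiling


@pytest.fixture(scope="session")
def cxcr3_protein() -> tiling.ProteinRecord:
    return tiling.ProteinRecord(cxcr3.CXCR3_ID, cxcr3.CXCR3_SEQUENCE)


@pytest.fixture(scope="session")
def cxcr3_tiles(cxcr3_protein):
    return tiling.tile_sequence(cxcr3_protein, window=20, step=10)


@pytest.fixture(scope="session")
def peptide_props() -> pd.DataFrame:
    return cxcr3.peptide_properties_frame()


@pytest.fixture(scope="session")
def small_dataset() -> simulate.SyntheticDataset:
    """Six-pair dataset with a known two-peptide epitope bump."""
    cfg = simulate.SyntheticConfig(
        n_pairs=6, seed=1234, sigma_s=0.0, epitope_spec=((33, 34, 1.5),)
    )
    return simulate.generate(cfg)


@pytest.fixture(scope="session")
def small_normalized(small_dataset) -> pd.DataFrame:
    kept, _ = elisa.preprocess(small_dataset.plate_table)
    return kept


def direct_model_dataset(rng, n_pairs=6, n_peptides=12, replicates=2,
                         sigma_s=0.5, rho_s=0.5):
    """Simulate logit readings directly from the signal model (no OD layer).

    Used to probe the sampler itself, bypassing the generator's OD mapping
    and per-plate re-normalization.
    Returns (normalized-style frame with replicates averaged, props, true f_s).
    """
    P = n_peptides
    pi = rng.uniform(3, 13, P)
    hyd = rng.uniform(-2, 2, P)
    z = lambda v: (v - v.mean()) / v.std()
    piz, hydz = z(pi), z(hyd)

    def ar1(rho, sig):
        f = np.empty(P)
        f[0] = rng.standard_normal() * sig
        for t in range(1, P):
            f[t] = rho * f[t - 1] + sig * np.sqrt(1 - rho**2) * rng.standard_normal()
        return f

    fbg = ar1(0.6, 0.6)
    fbg -= fbg.mean()
    fs = ar1(rho_s, sigma_s)
    rows = []
    for k in range(n_pairs):
        a = 0.3 * rng.standard_normal()
        for w, group in ((1.0, "case"), (0.0, "control")):
            b = 0.4 * rng.standard_normal()
            for p in range(P):
                y = np.mean([
                    -1.2 + 0.15 * piz[p] - 0.25 * hydz[p] + a + b
                    + fbg[p] + w * fs[p] + 0.4 * rng.standard_normal()
                    for _ in range(replicates)
                ])
                rows.append((f"pl{k}", f"s{k}{group}", group, p + 1, 1, y))
    df = pd.DataFrame(rows, columns=[
        "plate_id", "serum_id", "group", "peptide", "replicate", "y",
    ])
    props = pd.DataFrame(
        {"peptide": range(1, P + 1), "pi": pi, "gravy": hyd}
    ).set_index("peptide")
    return df, props, fs
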