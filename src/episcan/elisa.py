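"""Plate-structured peptide-ELISA data: schema, I/O, normalization, QC.

The experimental unit is a 96-well-style plate carrying one case and one
control serum, each probed against every array peptide (in duplicate) plus
positive-control and blank wells.  Raw OD450 readings are normalized per
plate to an open unit interval and logit-transformed; serum runs whose
logit signal barely varies across peptides are removed by an empirical
variance quantile filter before modeling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SCHEMA_COLUMNS = [
    "plate_id", "well", "role", "peptide", "serum_id", "group", "replicate", "od450",
]
ROLES = {"peptide", "positive_control", "blank"}
GROUPS = {"case", "control"}


@dataclass
class PlateTable:
    """Validated collection of well readings plus per-plate metadata."""

    data: pd.DataFrame
    n_peptides: int = field(init=False)

    def __post_init__(self) -> None:
        self.data = _validate(self.data)
        pep = self.data.loc[self.data["role"] == "peptide", "peptide"]
        self.n_peptides = int(pep.max()) if len(pep) else 0

    @property
    def plates(self) -> list[str]:
        return list(dict.fromkeys(self.data["plate_id"]))

    @property
    def sera(self) -> pd.DataFrame:
        """One row per serum: its group label."""
        s = self.data.dropna(subset=["serum_id"]).drop_duplicates("serum_id")
        return s[["serum_id", "group"]].reset_index(drop=True)


def _reject(row_number: int | None, message: str):
    where = "" if row_number is None else f" (row {row_number})"
    raise ValueError(message + where)


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        _reject(None, f"missing column(s): {missing}")
    df = df[SCHEMA_COLUMNS].copy()
    df["peptide"] = pd.array(
        [None if pd.isna(v) or v == "" else int(v) for v in df["peptide"]],
        dtype="Int64",
    )
    df["od450"] = pd.to_numeric(df["od450"])
    df["replicate"] = df["replicate"].astype(int)

    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = row 1
        if row.role not in ROLES:
            _reject(i, f"unknown role {row.role!r}")
        if row.group not in GROUPS:
            _reject(i, f"unknown group label {row.group!r}")
        if row.od450 < 0:
            _reject(i, f"negative od450 {row.od450}")
        if row.role == "peptide" and pd.isna(row.peptide):
            _reject(i, "peptide well without a peptide index")
        if row.replicate < 1:
            _reject(i, f"replicate must be >= 1, got {row.replicate}")

    dup = df.duplicated(subset=["plate_id", "well"])
    if dup.any():
        _reject(int(dup.idxmax()) + 2, "duplicate (plate, well)")

    pep = df.loc[df["role"] == "peptide", "peptide"]
    if len(pep):
        n_pep = int(pep.max())
        if int(pep.min()) < 1:
            _reject(None, "peptide indices must be >= 1")
        for plate, sub in df.groupby("plate_id", sort=False):
            if sub["serum_id"].nunique() > 2:
                _reject(None, f"plate {plate} carries more than 2 sera")
            if not (sub["role"] == "blank").any():
                _reject(None, f"plate {plate} has no blank well")
            if not (sub["role"] == "positive_control").any():
                _reject(None, f"plate {plate} has no positive-control well")
            counts = (
                sub[sub["role"] == "peptide"]
                .groupby(["serum_id", "peptide"], observed=True)
                .size()
            )
            if counts.nunique() > 1:
                _reject(None, f"plate {plate}: unequal replicate counts")
        _ = n_pep
    return df.reset_index(drop=True)


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_plate_table(path) -> PlateTable:
    """Read a delimited plate table (TSV default, CSV by extension)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    return PlateTable(df)


def write_plate_table(table: PlateTable, path) -> None:
    df = table.data.copy()
    df.to_csv(path, sep=_sep_for(path), index=False)


def normalize_plate(values) -> tuple[float, float, np.ndarray]:
    """Map a plate's OD vector into (0,1) by padded min/max limits.

    u = min/1.1 and o = max*1.1 guarantee every normalized value is strictly
    inside the unit interval; the map is invariant to rescaling all ODs by
    a positive constant.
    """
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise ValueError("all OD values must be positive (clamp zeros first)")
    if np.unique(x).size < 2:
        raise ValueError("normalization undefined for constant plate values")
    u = x.min() / 1.1
    o = x.max() * 1.1
    return u, o, (x - u) / (o - u)


def logit_transform(x_hat) -> np.ndarray:
    """y = ln(x/(1-x)) elementwise; requires every value in (0,1)."""
    x = np.asarray(x_hat, dtype=float)
    if np.any((x <= 0) | (x >= 1)):
        raise ValueError("logit requires values strictly inside (0, 1)")
    return np.log(x / (1.0 - x))


def clamp_nonpositive(od: pd.Series) -> pd.Series:
    """Replace OD <= 0 by half the smallest positive OD on the plate."""
    bad = od <= 0
    if bad.any():
        floor = od[~bad].min() * 0.5
        log.info("clamped %d non-positive OD values to %.4g", int(bad.sum()), floor)
        od = od.where(~bad, floor)
    return od


def normalize_table(
    table: PlateTable,
    include_controls: bool = True,
    average_replicates: bool = True,
) -> pd.DataFrame:
    """Per-plate normalization + logit for every peptide well.

    ``include_controls`` determines whether blank/positive-control wells
    enter the plate min/max (they are never emitted as observations).
    Duplicate wells are averaged on the OD scale first unless
    ``average_replicates`` is False.
    """
    out = []
    for plate, sub in table.data.groupby("plate_id", sort=False):
        sub = sub.copy()
        sub["od450"] = clamp_nonpositive(sub["od450"])
        pep = sub[sub["role"] == "peptide"].copy()
        if average_replicates:
            pep = (
                pep.groupby(["plate_id", "serum_id", "group", "peptide"],
                            observed=True, sort=True)["od450"]
                .mean()
                .reset_index()
            )
            pep["replicate"] = 1
        limits_source = sub if include_controls else sub[sub["role"] == "peptide"]
        ref = limits_source["od450"].to_numpy()
        if average_replicates:
            # limits from the same averaged scale as the observations
            ctrl = sub[sub["role"] != "peptide"]["od450"].to_numpy()
            ref = np.concatenate([pep["od450"].to_numpy(), ctrl]) \
                if include_controls else pep["od450"].to_numpy()
        u = ref.min() / 1.1
        o = ref.max() * 1.1
        pep["x_hat"] = (pep["od450"] - u) / (o - u)
        pep["y"] = logit_transform(pep["x_hat"].to_numpy())
        pep["u"] = u
        pep["o"] = o
        out.append(pep)
    cols = ["plate_id", "serum_id", "group", "peptide", "replicate",
            "od450", "x_hat", "y", "u", "o"]
    res = pd.concat(out, ignore_index=True)
    return res.sort_values(
        ["plate_id", "serum_id", "peptide", "replicate"]
    ).reset_index(drop=True)[cols]


def qc_variance_filter(
    normalized: pd.DataFrame, quantile: float = 0.25
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop low-variance serum runs.

    A serum run is one serum on one plate across its peptide wells
    (replicates averaged first).  Runs whose logit variance falls strictly
    below the empirical ``quantile`` (linear interpolation) of all run
    variances are removed.  Returns (kept observations, report) where the
    report lists every run with its variance and drop flag.
    """
    per_pep = normalized.groupby(
        ["plate_id", "serum_id", "peptide"], observed=True, sort=True
    )["y"].mean()
    per_run = per_pep.groupby(level=["plate_id", "serum_id"]).var(ddof=1)
    report = per_run.rename("variance").reset_index()
    if len(per_run) < 4:
        warnings.warn("fewer than 4 serum runs: variance quantile ill-determined; "
                      "keeping all runs")
        report["dropped"] = False
        return normalized.copy(), report
    cut = float(np.quantile(per_run.to_numpy(), quantile))
    report["dropped"] = report["variance"] < cut
    dropped_keys = set(
        map(tuple, report.loc[report["dropped"], ["plate_id", "serum_id"]].to_numpy())
    )
    keep_mask = [
        (p, s) not in dropped_keys
        for p, s in zip(normalized["plate_id"], normalized["serum_id"])
    ]
    return normalized[keep_mask].reset_index(drop=True), report


def preprocess(
    table: PlateTable,
    qc_quantile: float = 0.25,
    include_controls: bool = True,
    average_replicates: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """normalize_table + qc_variance_filter in one call."""
    normalized = normalize_table(table, include_controls, average_replicates)
    return qc_variance_filter(normalized, qc_quantile)
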