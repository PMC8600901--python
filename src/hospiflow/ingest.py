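"""Reading, validation and inclusion filtering of stay / registry tables.

Stay CSV columns
    patient_id, hospital_id, entry_date (ISO 8601), discharge_date,
    activity_domain, valid, iterative_treatment
Registry CSV columns
    hospital_id, rhg_id, excluded_reason, bed_count, rhg_leader

Malformed rows are never silently dropped: they are collected into a rejects
table with a reason per row.  The inclusion filters mirror a national
claims-database extraction: quality-control failures and iterative-treatment
stays are removed first, then hospitals flagged for exclusion in the
registry (overseas groups, psychiatric-only groups, the Paris single legal
entity), then same-day transfer stays whose own length of stay is under
48 h, and finally — on the counts that remain — hospitals with fewer than
500 annual stays.  Because the source carries dates (not times), length of
stay is 24 h x (discharge − entry): "< 48 h" means a date difference of 0
or 1 day.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

STAY_COLUMNS = (
    "patient_id",
    "hospital_id",
    "entry_date",
    "discharge_date",
    "activity_domain",
    "valid",
    "iterative_treatment",
)
REGISTRY_COLUMNS = ("hospital_id", "rhg_id", "excluded_reason", "bed_count", "rhg_leader")

_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f", ""}


class LoadResult(NamedTuple):
    stays: pd.DataFrame
    registry: pd.DataFrame
    rejects: pd.DataFrame


def _parse_bool(series: pd.Series) -> pd.Series:
    s = series.astype(str).str.strip().str.lower()
    out = pd.Series(pd.NA, index=series.index, dtype="boolean")
    out[s.isin(_TRUTHY)] = True
    out[s.isin(_FALSY)] = False
    return out


def load_registry(path) -> pd.DataFrame:
    """Load and validate the hospital registry CSV."""
    registry = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("hospital_id", "rhg_id"):
        if col not in registry.columns:
            raise ValueError(f"registry is missing required column '{col}'")
    if registry["hospital_id"].duplicated().any():
        dupes = registry.loc[registry["hospital_id"].duplicated(), "hospital_id"].tolist()
        raise ValueError(f"duplicate hospital_id in registry: {dupes[:5]}")
    registry = registry.copy()
    if "excluded_reason" not in registry.columns:
        registry["excluded_reason"] = ""
    if "bed_count" in registry.columns:
        registry["bed_count"] = pd.to_numeric(registry["bed_count"], errors="coerce")
    else:
        registry["bed_count"] = np.nan
    if "rhg_leader" in registry.columns:
        registry["rhg_leader"] = _parse_bool(registry["rhg_leader"]).fillna(False).astype(bool)
    else:
        registry["rhg_leader"] = False
    return registry


def load_stays(path, registry_path) -> LoadResult:
    """Load and validate the stay and registry CSVs.

    Raises on structural problems (missing columns, duplicate registry ids);
    per-row problems (unparseable dates, negative length of stay, missing
    identifiers, bad boolean flags) go to the rejects table with a reason.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in STAY_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"stay table is missing required column '{col}'")

    registry = load_registry(registry_path)

    entry = pd.to_datetime(raw["entry_date"], errors="coerce", format="ISO8601")
    disch = pd.to_datetime(raw["discharge_date"], errors="coerce", format="ISO8601")
    valid = _parse_bool(raw["valid"])
    iterative = _parse_bool(raw["iterative_treatment"])

    reasons = pd.Series("", index=raw.index, dtype=object)
    reasons[(raw["patient_id"].str.strip() == "") | (raw["hospital_id"].str.strip() == "")] = (
        "missing identifier"
    )
    reasons[entry.isna()] = "unparseable entry_date"
    reasons[disch.isna()] = "unparseable discharge_date"
    reasons[valid.isna() | iterative.isna()] = "invalid boolean flag"
    neg = entry.notna() & disch.notna() & (disch < entry)
    reasons[neg] = "negative length of stay"

    bad = reasons != ""
    rejects = raw.loc[bad].copy()
    rejects["reason"] = reasons[bad]

    stays = pd.DataFrame(
        {
            "patient_id": raw.loc[~bad, "patient_id"],
            "hospital_id": raw.loc[~bad, "hospital_id"],
            "entry_date": entry[~bad],
            "discharge_date": disch[~bad],
            "activity_domain": raw.loc[~bad, "activity_domain"],
            "valid": valid[~bad].astype(bool),
            "iterative_treatment": iterative[~bad].astype(bool),
        }
    ).reset_index(drop=True)
    return LoadResult(stays, registry, rejects.reset_index(drop=True))


def _transfer_short_stay_mask(stays: pd.DataFrame, los_min_hours: float) -> pd.Series:
    """True where a stay is a received transfer with LOS below the threshold.

    A stay is a transfer iff the same patient was discharged from a
    *different* hospital on the stay's entry date.  LOS in hours is
    24 x (discharge − entry) days.
    """
    los_days = (stays["discharge_date"] - stays["entry_date"]).dt.days
    short = (24 * los_days) < los_min_hours
    senders = stays[["patient_id", "hospital_id", "discharge_date"]].rename(
        columns={"hospital_id": "sender_hospital", "discharge_date": "sender_discharge"}
    )
    recv = stays[["patient_id", "hospital_id", "entry_date"]].reset_index(names="_row")
    merged = recv.merge(
        senders,
        left_on=["patient_id", "entry_date"],
        right_on=["patient_id", "sender_discharge"],
        how="inner",
    )
    merged = merged[merged["sender_hospital"] != merged["hospital_id"]]
    is_transfer = pd.Series(False, index=stays.index)
    is_transfer.loc[merged["_row"].unique()] = True
    return is_transfer & short


def apply_exclusions(
    stays: pd.DataFrame,
    registry: pd.DataFrame,
    min_annual_stays: int = 500,
    receiving_los_min_hours: float = 48,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the inclusion rules in order; return (filtered stays, ledger).

    Order: invalid stays -> iterative-treatment stays -> registry-flagged
    hospitals -> short received transfers -> low-volume hospitals (computed
    on the counts remaining after the other filters).  The ledger records
    rows removed per rule, so rows_in == rows_out + ledger total.
    """
    ledger: list[tuple[str, int]] = []
    df = stays

    m = ~df["valid"]
    ledger.append(("invalid_stay", int(m.sum())))
    df = df.loc[~m]

    m = df["iterative_treatment"]
    ledger.append(("iterative_treatment", int(m.sum())))
    df = df.loc[~m]

    flagged = set(
        registry.loc[
            registry["excluded_reason"].astype(str).str.strip() != "", "hospital_id"
        ]
    )
    m = df["hospital_id"].isin(flagged)
    ledger.append(("registry_excluded_hospital", int(m.sum())))
    df = df.loc[~m]

    m = _transfer_short_stay_mask(df.reset_index(drop=True), receiving_los_min_hours)
    m.index = df.index
    ledger.append(("short_transfer", int(m.sum())))
    df = df.loc[~m]

    counts = df.groupby("hospital_id", observed=True)["hospital_id"].transform("size")
    m = counts < min_annual_stays
    ledger.append(("min_annual_stays", int(m.sum())))
    df = df.loc[~m]

    ledger_df = pd.DataFrame(ledger, columns=["rule", "n_removed"])
    return df.reset_index(drop=True), ledger_df
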