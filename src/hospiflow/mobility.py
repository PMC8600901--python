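"""Inter-hospital patient mobility detection.

A mobility event links an index stay to the *earliest* subsequent stay of
the same patient in a different hospital whose entry date falls within a
90-day window of the index discharge.  A gap of 0 days (entry on the day of
discharge) is a transfer; a positive gap is a readmission.  Each index stay
yields at most one event, so chains A -> B -> C count as two events (A->B
and B->C), never three.

The window is measured discharge-to-entry in whole days.  A subsequent stay
in a different hospital that *begins before the index discharge* (overlapping
hospitalizations) is anomalous in discharge data; such index stays produce
no event and are tallied in the diagnostics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EVENT_COLUMNS = (
    "patient_id",
    "from_hospital",
    "to_hospital",
    "index_discharge_date",
    "next_entry_date",
    "gap_days",
    "same_rhg",
    "is_transfer",
)


def _rhg_map(registry: pd.DataFrame) -> dict:
    return dict(zip(registry["hospital_id"], registry["rhg_id"]))


def detect_mobility(
    stays: pd.DataFrame,
    registry: pd.DataFrame,
    window_days: int = 90,
    mode: str = "first",
) -> tuple[pd.DataFrame, dict]:
    """Detect mobility events among a patient's stays.

    Parameters
    ----------
    stays : DataFrame
        Filtered stay table (see :mod:`hospiflow.ingest` for columns).
    registry : DataFrame
        Hospital registry; supplies the regional-group id for ``same_rhg``.
    window_days : int
        Maximum allowed gap, in whole days, between index discharge and the
        next entry (inclusive).
    mode : {"first", "all"}
        ``"first"`` (default) emits at most one event per index stay — the
        earliest qualifying follow-up, ties on entry date broken by receiving
        hospital id.  ``"all"`` emits every qualifying ordered pair, for
        sensitivity analysis.

    Returns
    -------
    (events, diagnostics)
        ``events`` has one row per event (columns ``EVENT_COLUMNS``);
        ``diagnostics`` is a dict with the overlap-skip count and a flag
        count of index stays discharged within ``window_days`` of the end of
        the observation period (their follow-ups may be censored).
    """
    if mode not in ("first", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    if window_days <= 0:
        raise ValueError("window_days must be positive")

    rhg = _rhg_map(registry)

    df = stays.sort_values(
        ["patient_id", "entry_date", "hospital_id"], kind="mergesort"
    ).reset_index(drop=True)

    # only patients with >=2 stays can generate events
    multi = df["patient_id"].duplicated(keep=False)
    n_overlap = 0
    rows: list[tuple] = []

    if multi.any():
        sub = df.loc[multi]
        pid = sub["patient_id"].to_numpy()
        hosp = sub["hospital_id"].to_numpy()
        entry = sub["entry_date"].to_numpy().astype("datetime64[D]").astype(np.int64)
        disch = sub["discharge_date"].to_numpy().astype("datetime64[D]").astype(np.int64)
        # group boundaries over the sorted patient column
        starts = np.flatnonzero(np.r_[True, pid[1:] != pid[:-1]])
        ends = np.r_[starts[1:], pid.size]
        for s, e in zip(starts, ends):
            for i in range(s, e):
                d_i = disch[i]
                overlap = False
                best = None  # (entry, hospital, j)
                for j in range(s, e):
                    if j == i or hosp[j] == hosp[i]:
                        continue
                    e_j = entry[j]
                    if entry[i] <= e_j < d_i:
                        overlap = True
                        continue
                    gap = e_j - d_i
                    if 0 <= gap <= window_days:
                        key = (e_j, hosp[j])
                        if mode == "all":
                            rows.append((i, j, gap))
                        elif best is None or key < (best[0], best[1]):
                            best = (e_j, hosp[j], j)
                if overlap and mode == "first":
                    n_overlap += 1
                    continue
                if overlap and mode == "all":
                    n_overlap += 1
                if mode == "first" and best is not None:
                    rows.append((i, best[2], best[0] - d_i))

        if rows:
            ii = np.array([r[0] for r in rows])
            jj = np.array([r[1] for r in rows])
            gaps = np.array([r[2] for r in rows], dtype=int)
            events = pd.DataFrame(
                {
                    "patient_id": pid[ii],
                    "from_hospital": hosp[ii],
                    "to_hospital": hosp[jj],
                    "index_discharge_date": sub["discharge_date"].to_numpy()[ii],
                    "next_entry_date": sub["entry_date"].to_numpy()[jj],
                    "gap_days": gaps,
                }
            )
        else:
            events = _empty_events()
    else:
        events = _empty_events()

    if len(events):
        events["same_rhg"] = (
            events["from_hospital"].map(rhg).to_numpy()
            == events["to_hospital"].map(rhg).to_numpy()
        )
        events["is_transfer"] = events["gap_days"] == 0

    horizon = stays["discharge_date"].max()
    censored = int((stays["discharge_date"] > horizon - pd.Timedelta(days=window_days)).sum())
    diagnostics = {
        "n_index_stays": int(len(stays)),
        "n_events": int(len(events)),
        "n_overlap_skipped": int(n_overlap),
        "n_stays_in_censoring_window": censored,
        "window_days": int(window_days),
        "mode": mode,
    }
    return events, diagnostics


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": pd.Series(dtype=object),
            "from_hospital": pd.Series(dtype=object),
            "to_hospital": pd.Series(dtype=object),
            "index_discharge_date": pd.Series(dtype="datetime64[ns]"),
            "next_entry_date": pd.Series(dtype="datetime64[ns]"),
            "gap_days": pd.Series(dtype=int),
            "same_rhg": pd.Series(dtype=bool),
            "is_transfer": pd.Series(dtype=bool),
        }
    )


def mobility_index(
    events: pd.DataFrame, stays: pd.DataFrame, registry: pd.DataFrame
) -> pd.Series:
    """Same-group mobility index per hospital, in percent.

    For hospital *h*: 100 x (stays at *h* followed by a stay in another
    hospital of the same regional group within the window) / (stays at *h*).
    Because each stay carries at most one event, the numerator is the count
    of same-group events whose sending hospital is *h*.
    """
    denom = stays.groupby("hospital_id", observed=True).size()
    if len(events):
        num = (
            events.loc[events["same_rhg"]]
            .groupby("from_hospital", observed=True)
            .size()
            .reindex(denom.index, fill_value=0)
        )
    else:
        num = pd.Series(0, index=denom.index)
    idx = 100.0 * num / denom
    idx.name = "mobility_index_pct"
    idx.index.name = "hospital_id"
    return idx


def window_profile(
    events: pd.DataFrame, cutoffs: list[int] = (0, 1, 7, 30, 60, 90)
) -> pd.Series:
    """Cumulative share of events with gap <= each cutoff.

    Non-decreasing by construction; the final cutoff (the window itself)
    yields 1.0.
    """
    if events is None or len(events) == 0:
        raise ValueError("window_profile: empty event list")
    gaps = events["gap_days"].to_numpy()
    out = pd.Series(
        {c: float((gaps <= c).mean()) for c in cutoffs}, name="cumulative_share"
    )
    out.index.name = "gap_days_cutoff"
    return out


def within_rhg_share(events: pd.DataFrame, min_pair_weight: int = 0) -> float:
    """Fraction of mobility occurring inside regional hospital groups.

    With ``min_pair_weight`` > 0 the share is computed only over events on
    hospital pairs (unordered) whose total event count reaches the threshold
    — the "relations with at least N patients" restriction.
    """
    if events is None or len(events) == 0:
        raise ValueError("within_rhg_share: empty event list")
    ev = events
    if min_pair_weight > 0:
        a = ev[["from_hospital", "to_hospital"]].to_numpy()
        lo = np.minimum(a[:, 0], a[:, 1])
        hi = np.maximum(a[:, 0], a[:, 1])
        pair = pd.Series(list(zip(lo, hi)))
        weights = pair.map(pair.value_counts())
        ev = ev.loc[(weights >= min_pair_weight).to_numpy()]
        if len(ev) == 0:
            raise ValueError("within_rhg_share: no events survive the pair-weight restriction")
    return float(ev["same_rhg"].mean())
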