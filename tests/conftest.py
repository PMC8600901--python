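import numpy as np
import pandas as pd
import pytest


def make_stays(rows):
    """Build a stay table from (patient, hospital, entry, discharge, domain) tuples.

    Optional 6th/7th elements set the valid / iterative flags.
    """
    recs = []
    for r in rows:
        patient, hospital, entry, discharge, domain = r[:5]
        valid = r[5] if len(r) > 5 else True
        iterative = r[6] if len(r) > 6 else False
        recs.append(
            {
                "patient_id": patient,
                "hospital_id": hospital,
                "entry_date": pd.Timestamp(entry),
                "discharge_date": pd.Timestamp(discharge),
                "activity_domain": domain,
                "valid": valid,
                "iterative_treatment": iterative,
            }
        )
    return pd.DataFrame(recs)


def make_registry(hospital_rhg, excluded=(), leaders=(), beds=None):
    """Build a registry from a {hospital: rhg} mapping."""
    rows = []
    for h, g in hospital_rhg.items():
        rows.append(
            {
                "hospital_id": h,
                "rhg_id": g,
                "excluded_reason": "excluded" if h in excluded else "",
                "bed_count": (beds or {}).get(h, 100),
                "rhg_leader": h in leaders,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20160101)


def random_stay_table(rng, n_stays=40, n_patients=8, n_hospitals=3, n_days=365):
    """Random small stay table for oracle comparisons."""
    entry = rng.integers(0, n_days, size=n_stays)
    los = rng.integers(0, 10, size=n_stays)
    base = pd.Timestamp("2016-01-01")
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in rng.integers(0, n_patients, size=n_stays)],
            "hospital_id": [f"H{i}" for i in rng.integers(0, n_hospitals, size=n_stays)],
            "entry_date": [base + pd.Timedelta(days=int(d)) for d in entry],
            "discharge_date": [
                base + pd.Timedelta(days=int(d + l)) for d, l in zip(entry, los)
            ],
            "activity_domain": "AD0",
            "valid": True,
            "iterative_treatment": False,
        }
    )
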