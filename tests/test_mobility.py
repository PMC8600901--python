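import numpy as np
import pandas as pd
import pytest

from hospiflow.mobility import (
    detect_mobility,
    mobility_index,
    window_profile,
    within_rhg_share,
)

from .conftest import make_registry, make_stays, random_stay_table


def brute_force_events(stays, registry, window_days=90):
    """Quadratic all-pairs oracle for mobility detection.

    For every index stay, scan *all* other stays of the same patient and
    apply the definitions directly: overlap (a different-hospital stay
    beginning in [entry, discharge)) suppresses the event; otherwise the
    earliest follow-up with 0 <= gap <= window wins, ties broken by
    receiving hospital id.
    """
    rhg = dict(zip(registry["hospital_id"], registry["rhg_id"]))
    out = []
    df = stays.reset_index(drop=True)
    for i, s in df.iterrows():
        candidates = []
        overlap = False
        for j, t in df.iterrows():
            if i == j or t["patient_id"] != s["patient_id"]:
                continue
            if t["hospital_id"] == s["hospital_id"]:
                continue
            if s["entry_date"] <= t["entry_date"] < s["discharge_date"]:
                overlap = True
                continue
            gap = (t["entry_date"] - s["discharge_date"]).days
            if 0 <= gap <= window_days:
                candidates.append((t["entry_date"], t["hospital_id"], gap))
        if overlap or not candidates:
            continue
        entry, hosp, gap = min(candidates)
        out.append(
            (
                s["patient_id"],
                s["hospital_id"],
                hosp,
                gap,
                rhg[s["hospital_id"]] == rhg[hosp],
            )
        )
    return sorted(out)


def as_tuples(events):
    return sorted(
        zip(
            events["patient_id"],
            events["from_hospital"],
            events["to_hospital"],
            events["gap_days"],
            events["same_rhg"],
        )
    )


REGISTRY = make_registry({f"H{i}": f"R{i % 2}" for i in range(5)})


class TestDetectMobility:
    def test_single_stay_patient_has_no_event(self):
        stays = make_stays([("P1", "H1", "2016-01-01", "2016-01-05", "AD0")])
        events, diag = detect_mobility(stays, REGISTRY)
        assert len(events) == 0
        assert diag["n_overlap_skipped"] == 0

    def test_window_boundary_at_90_days(self):
        base = [("P1", "H1", "2016-02-27", "2016-03-01", "AD0")]
        inside = make_stays(base + [("P1", "H2", "2016-05-30", "2016-06-03", "AD0")])
        outside = make_stays(base + [("P1", "H2", "2016-05-31", "2016-06-03", "AD0")])
        ev_in, _ = detect_mobility(inside, REGISTRY)
        ev_out, _ = detect_mobility(outside, REGISTRY)
        assert len(ev_in) == 1 and ev_in["gap_days"].iloc[0] == 90
        assert len(ev_out) == 0

    def test_same_day_tie_broken_by_hospital_id(self):
        stays = make_stays(
            [
                ("P1", "H2", "2016-01-01", "2016-01-04", "AD0"),
                ("P1", "H3", "2016-01-10", "2016-01-12", "AD0"),
                ("P1", "H1", "2016-01-10", "2016-01-12", "AD0"),
            ]
        )
        events, _ = detect_mobility(stays, REGISTRY)
        ev = events[events["from_hospital"] == "H2"]
        assert list(ev["to_hospital"]) == ["H1"]

    def test_transfer_is_gap_zero(self):
        stays = make_stays(
            [
                ("P1", "H1", "2016-01-01", "2016-01-05", "AD0"),
                ("P1", "H2", "2016-01-05", "2016-01-09", "AD0"),
            ]
        )
        events, _ = detect_mobility(stays, REGISTRY)
        assert bool(events["is_transfer"].iloc[0]) is True
        assert events["gap_days"].iloc[0] == 0

    def test_overlapping_stay_suppresses_event_and_is_diagnosed(self):
        stays = make_stays(
            [
                ("P1", "H1", "2016-01-01", "2016-01-10", "AD0"),
                ("P1", "H2", "2016-01-05", "2016-01-20", "AD0"),
            ]
        )
        events, diag = detect_mobility(stays, REGISTRY)
        assert len(events[events["from_hospital"] == "H1"]) == 0
        assert diag["n_overlap_skipped"] >= 1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_quadratic_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        stays = random_stay_table(rng, n_stays=50, n_patients=10, n_hospitals=5, n_days=250)
        events, _ = detect_mobility(stays, REGISTRY)
        assert as_tuples(events) == brute_force_events(stays, REGISTRY)

    def test_six_stay_fixture_matches_oracle(self):
        stays = make_stays(
            [
                ("P1", "H1", "2016-01-01", "2016-01-03", "AD0"),
                ("P1", "H2", "2016-01-03", "2016-01-10", "AD0"),
                ("P1", "H3", "2016-03-01", "2016-03-02", "AD0"),
                ("P2", "H1", "2016-06-01", "2016-06-02", "AD0"),
                ("P2", "H1", "2016-06-10", "2016-06-12", "AD0"),
                ("P2", "H3", "2016-07-01", "2016-07-05", "AD0"),
            ]
        )
        events, _ = detect_mobility(stays, REGISTRY)
        assert as_tuples(events) == brute_force_events(stays, REGISTRY)

    def test_event_set_invariant_under_row_shuffling(self, rng):
        stays = random_stay_table(rng, n_stays=40)
        a, _ = detect_mobility(stays, REGISTRY)
        b, _ = detect_mobility(stays.sample(frac=1, random_state=3), REGISTRY)
        assert as_tuples(a) == as_tuples(b)


class TestMobilityIndex:
    def test_eleven_percent_example(self):
        # 100 stays at H0, 11 followed by a same-group stay elsewhere
        rows = []
        for i in range(11):
            rows.append((f"P{i}", "H0", "2016-01-01", "2016-01-05", "AD0"))
            rows.append((f"P{i}", "H2", "2016-02-01", "2016-02-05", "AD0"))  # same RHG (even)
        for i in range(11, 100):
            rows.append((f"P{i}", "H0", "2016-01-01", "2016-01-05", "AD0"))
        stays = make_stays(rows)
        events, _ = detect_mobility(stays, REGISTRY)
        idx = mobility_index(events, stays, REGISTRY)
        assert idx["H0"] == pytest.approx(11.0)

    def test_out_of_group_mobility_scores_zero(self):
        rows = [
            ("P1", "H0", "2016-01-01", "2016-01-05", "AD0"),
            ("P1", "H1", "2016-02-01", "2016-02-05", "AD0"),  # H0 in R0, H1 in R1
        ]
        stays = make_stays(rows)
        events, _ = detect_mobility(stays, REGISTRY)
        assert len(events) == 1
        idx = mobility_index(events, stays, REGISTRY)
        assert idx["H0"] == 0.0

    def test_hospital_with_no_events_scores_zero(self):
        stays = make_stays([("P1", "H1", "2016-01-01", "2016-01-05", "AD0")])
        events, _ = detect_mobility(stays, REGISTRY)
        idx = mobility_index(events, stays, REGISTRY)
        assert idx["H1"] == 0.0


class TestWindowProfile:
    def test_hand_counted_profile(self):
        events = pd.DataFrame({"gap_days": [0, 0, 5, 40, 89]})
        prof = window_profile(events)
        assert list(prof) == pytest.approx([0.4, 0.4, 0.6, 0.6, 0.8, 1.0])

    def test_all_transfers(self):
        prof = window_profile(pd.DataFrame({"gap_days": [0, 0, 0]}))
        assert (prof == 1.0).all()

    def test_monotone_and_ends_at_one(self, rng):
        events = pd.DataFrame({"gap_days": rng.integers(0, 91, size=200)})
        prof = window_profile(events)
        assert (prof.diff().dropna() >= 0).all()
        assert prof.iloc[-1] == 1.0

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError):
            window_profile(pd.DataFrame({"gap_days": []}))


class TestWithinRhgShare:
    def _events(self, pairs):
        return pd.DataFrame(
            {
                "from_hospital": [p[0] for p in pairs],
                "to_hospital": [p[1] for p in pairs],
                "same_rhg": [p[2] for p in pairs],
            }
        )

    def test_all_within(self):
        assert within_rhg_share(self._events([("A", "B", True)] * 4)) == 1.0

    def test_nine_of_twenty(self):
        ev = self._events([("A", "B", True)] * 9 + [("A", "C", False)] * 11)
        assert within_rhg_share(ev) == pytest.approx(0.45)

    def test_pair_weight_restriction_can_move_share_either_way(self):
        # heavy within-group pair + light across-group pair: share rises
        up = self._events([("A", "B", True)] * 5 + [("A", "C", False)])
        assert within_rhg_share(up, min_pair_weight=5) > within_rhg_share(up)
        # heavy across-group pair + light within-group pair: share falls
        down = self._events([("A", "C", False)] * 5 + [("A", "B", True)])
        assert within_rhg_share(down, min_pair_weight=5) < within_rhg_share(down)

    def test_empty_after_restriction_rejected(self):
        with pytest.raises(ValueError):
            within_rhg_share(self._events([("A", "B", True)]), min_pair_weight=10)
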