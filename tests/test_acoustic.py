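import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_associations, make_random_events
from sealassoc.acoustic import (cluster_associations, event_separations,
                                filter_false_detections, locate_associations,
                                pair_events, read_detection_log)
from sealassoc.timebase import to_iso


def write_log(path, rows):
    with open(path, "w") as fh:
        fh.write("receiver_id,timestamp,transmitter_id,valid\n")
        for r in rows:
            fh.write(",".join(str(v) for v in r) + "\n")


class TestReadDetectionLog:
    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "d.csv"
        write_log(p, [])
        df = read_detection_log(p)
        assert len(df) == 0 and df.attrs["n_skipped"] == 0

    def test_records_sorted_per_receiver(self, tmp_path):
        p = tmp_path / "d.csv"
        write_log(p, [("a", to_iso(300), "b", 1), ("a", to_iso(100), "b", 1),
                      ("a", to_iso(200), "c", 1)])
        df = read_detection_log(p)
        assert list(df["t"]) == [100.0, 200.0, 300.0]

    def test_malformed_timestamp_skipped_and_counted(self, tmp_path):
        p = tmp_path / "d.csv"
        rows = [("a", to_iso(60.0 * i), "b", 1) for i in range(9)]
        rows.insert(4, ("a", "not-a-time", "b", 1))
        write_log(p, rows)
        df = read_detection_log(p)
        assert len(df) == 9 and df.attrs["n_skipped"] == 1

    def test_wrong_header_is_hard_error(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("receiver,when,code\n")
        with pytest.raises(ValueError):
            read_detection_log(p)


class TestFilterFalseDetections:
    def test_all_valid_is_identity(self):
        df = pd.DataFrame({"receiver_id": ["a"] * 5, "t": np.arange(5.0),
                           "transmitter_id": ["b"] * 5, "valid": 1})
        kept, removed = filter_false_detections(df)
        assert removed == 0 and len(kept) == 5

    def test_flagged_counts_match(self):
        # 26 invalid among 1918 -> 1892 kept
        n = 1918
        valid = np.ones(n, dtype=int)
        valid[np.arange(0, 26 * 70, 70)] = 0
        df = pd.DataFrame({"receiver_id": ["a"] * n,
                           "t": np.arange(n, dtype=float) * 30,
                           "transmitter_id": ["b"] * n, "valid": valid})
        kept, removed = filter_false_detections(df)
        assert removed == 26 and len(kept) == 1892

    def test_heuristic_flags_isolated_record(self):
        t = np.array([0.0, 60.0, 120.0, 50_000.0])  # last is isolated
        df = pd.DataFrame({"receiver_id": ["a"] * 4, "t": t,
                           "transmitter_id": ["b"] * 4, "valid": 1})
        kept, removed = filter_false_detections(df, heuristic=True)
        assert removed == 1 and 50_000.0 not in kept["t"].values


class TestPairEvents:
    def make(self, rows):
        return pd.DataFrame(rows, columns=["receiver_id", "t",
                                           "transmitter_id", "valid"])

    def test_reciprocal_within_tolerance_one_two_way_event(self):
        df = self.make([("a", 100.0, "b", 1), ("b", 150.0, "a", 1)])
        ev = pair_events(df, tolerance=180.0)
        assert len(ev) == 1 and ev.loc[0, "two_way"]
        assert ev.loc[0, "t"] == 100.0

    def test_gap_beyond_tolerance_two_one_way_events(self):
        df = self.make([("a", 100.0, "b", 1), ("b", 300.0, "a", 1)])
        ev = pair_events(df, tolerance=180.0)
        assert len(ev) == 2 and not ev["two_way"].any()

    def test_two_way_fraction_matches_construction(self):
        # 970 of 1000 transmissions get a reciprocal record
        rng = np.random.default_rng(0)
        t = np.arange(1000) * 400.0
        rows = [("b", ti, "a", 1) for ti in t]
        paired = rng.choice(1000, 970, replace=False)
        rows += [("a", t[i] + 40.0, "b", 1) for i in paired]
        ev = pair_events(self.make(rows))
        frac = ev["two_way"].mean()
        assert ev["two_way"].sum() == 970
        assert abs(frac - 0.97) < 0.01

    def test_no_record_used_twice(self):
        # two a-side records compete for one reciprocal
        df = self.make([("a", 100.0, "b", 1), ("a", 160.0, "b", 1),
                        ("b", 130.0, "a", 1)])
        ev = pair_events(df, tolerance=180.0)
        assert len(ev) == 2 and ev["two_way"].sum() == 1

    def test_symmetric_under_log_swap(self):
        rng = np.random.default_rng(5)
        rows = [("a" if rng.random() < 0.5 else "b", float(t), None, 1)
                for t in np.sort(rng.uniform(0, 20_000, 60))]
        rows = [(r, t, ("b" if r == "a" else "a"), v) for r, t, _, v in rows]
        ev1 = pair_events(self.make(rows))
        ev2 = pair_events(self.make(rows[::-1]))
        pd.testing.assert_frame_equal(ev1, ev2)


class TestClusterAssociations:
    def events(self, minutes, dyad=("a", "b")):
        return pd.DataFrame({"seal_a": dyad[0], "seal_b": dyad[1],
                             "t": np.asarray(minutes, dtype=float) * 60.0,
                             "two_way": True})

    def test_single_event_gets_three_minute_duration(self):
        assoc = cluster_associations(self.events([10.0]))
        assert len(assoc) == 1
        assert assoc.loc[0, "duration_h"] == pytest.approx(3.0 / 60.0)

    def test_sub_threshold_gaps_stay_together(self):
        assoc = cluster_associations(self.events([0.0, 29.0, 58.0]))
        assert len(assoc) == 1
        assert assoc.loc[0, "duration_h"] == pytest.approx(58.0 / 60.0)

    def test_gap_exactly_at_threshold_does_not_split(self):
        assoc = cluster_associations(self.events([0.0, 30.0]))
        assert len(assoc) == 1

    def test_gap_beyond_threshold_splits(self):
        assoc = cluster_associations(self.events([0.0, 30.0 + 1e-6]))
        assert len(assoc) == 2

    def test_empty_input_empty_output(self):
        ev = self.events([])
        assert len(cluster_associations(ev)) == 0

    def test_matches_brute_force_on_random_streams(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            ev = make_random_events(rng, int(rng.integers(1, 51)))
            assoc = cluster_associations(ev)
            got = sorted(map(tuple, assoc[["seal_a", "seal_b", "start", "end",
                                           "n_events", "duration_h"]]
                             .itertuples(index=False)))
            assert got == sorted(brute_force_associations(ev))

    def test_partition_and_count_conservation(self):
        rng = np.random.default_rng(1)
        ev = make_random_events(rng, 400)
        assoc = cluster_associations(ev)
        # every event in exactly one association
        assert ev["assoc_id"].notna().all()
        counts = ev.groupby("assoc_id").size()
        assert (assoc.set_index("assoc_id")["n_events"]
                .sort_index().equals(counts.sort_index()))
        # intervals disjoint and separated by > threshold per dyad
        for _, grp in assoc.groupby(["seal_a", "seal_b"]):
            g = grp.sort_values("start")
            gaps = g["start"].to_numpy()[1:] - g["end"].to_numpy()[:-1]
            assert (gaps > 30.0 * 60.0).all()


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=40))
def test_cluster_oracle_property(times):
    ev = pd.DataFrame({"seal_a": "x", "seal_b": "y",
                       "t": np.sort(np.asarray(times)), "two_way": True})
    assoc = cluster_associations(ev)
    got = sorted(map(tuple, assoc[["seal_a", "seal_b", "start", "end",
                                   "n_events", "duration_h"]]
                     .itertuples(index=False)))
    assert got == sorted(brute_force_associations(ev))


class TestLocations:
    def gps(self, sid, t, lon, lat):
        return pd.DataFrame({"seal_id": sid, "t": t, "lon": lon, "lat": lat})

    def test_linear_midpoint_interpolation(self):
        assoc = pd.DataFrame({"assoc_id": [0], "seal_a": ["a"], "seal_b": ["b"],
                              "start": [0.0], "end": [600.0], "n_events": [2],
                              "duration_h": [600 / 3600]})
        ev = pd.DataFrame({"seal_a": ["a", "a"], "seal_b": ["b", "b"],
                           "t": [0.0, 600.0], "two_way": True,
                           "assoc_id": [0, 0]})
        gps = {"a": self.gps("a", [0.0, 600.0], [0.0, 0.1], [44.0, 44.0]),
               "b": self.gps("b", [0.0, 600.0], [0.0, 0.1], [44.001, 44.001])}
        out = locate_associations(assoc, ev, gps)
        assert out.loc[0, "lon_a"] == pytest.approx(0.05)
        assert out.loc[0, "lat_a"] == pytest.approx(44.0)

    def test_unbracketed_midpoint_gives_missing_location(self):
        assoc = pd.DataFrame({"assoc_id": [0], "seal_a": ["a"], "seal_b": ["b"],
                              "start": [0.0], "end": [100.0], "n_events": [1],
                              "duration_h": [0.05]})
        ev = pd.DataFrame({"seal_a": ["a"], "seal_b": ["b"], "t": [50.0],
                           "two_way": True, "assoc_id": [0]})
        gps = {"a": self.gps("a", [200.0, 400.0], [0.0, 0.1], [44.0, 44.0]),
               "b": self.gps("b", [0.0, 400.0], [0.0, 0.1], [44.0, 44.0])}
        out = locate_associations(assoc, ev, gps)
        assert np.isnan(out.loc[0, "lon_a"])
        assert np.isfinite(out.loc[0, "lon_b"])
        assert np.isnan(out.loc[0, "separation_km"])


class TestEventSeparations:
    def test_colocated_pair_separations_near_zero(self):
        t = np.arange(0.0, 3600.0, 300.0)
        gps = {"a": pd.DataFrame({"seal_id": "a", "t": t, "lon": -60.0,
                                  "lat": 44.0}),
               "b": pd.DataFrame({"seal_id": "b", "t": t, "lon": -60.0,
                                  "lat": 44.0})}
        ev = pd.DataFrame({"seal_a": "a", "seal_b": "b",
                           "t": [600.0, 1500.0], "two_way": True})
        sep = event_separations(ev, gps)
        assert np.allclose(sep, 0.0)

    def test_median_of_constructed_set(self):
        assert float(np.median([0.1, 0.15, 0.2])) == pytest.approx(0.15)
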