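import dataclasses
import filecmp

import numpy as np
import pandas as pd
import pytest

from sealassoc.ascii_grid import depth_at, read_ascii_grid
from sealassoc.geo import haversine_m
from sealassoc.synthdata import (SimConfig, make_scenario, simulate_acoustics,
                                 simulate_bathymetry, simulate_gps,
                                 simulate_latent_tracks,
                                 true_proximity_intervals)


def hourly_displacements(track):
    lon = track.minute_lon[::60]
    lat = track.minute_lat[::60]
    return haversine_m(lon[:-1], lat[:-1], lon[1:], lat[1:])


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"state_transition": ((0.5, 0.6), (0.2, 0.8))},
        {"lambda_slow": 0.0},
        {"lambda_slow": 5000.0},            # violates slow < fast
        {"tx_gap_min": 200.0},              # violates min < max
        {"pair_prob": 1.5},
        {"gps_interval": 7},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs).validate()


class TestLatentTracks:
    def test_zero_seals_gives_empty_list(self):
        assert simulate_latent_tracks(SimConfig(n_seals=0)) == []

    def test_identity_chain_stays_slow(self):
        cfg = SimConfig(n_seals=1, duration_days=2.0,
                        state_transition=((1.0, 0.0), (0.0, 1.0)), seed=5)
        (track,) = simulate_latent_tracks(cfg)
        assert (track.states == 0).all()

    def test_emission_means_calibrated(self):
        # free movement (no bank pull, no heading persistence): mean hourly
        # displacement per latent state converges to the exponential mean;
        # 5e4 hours keeps the Monte-Carlo error well inside the 2% band
        cfg = SimConfig(n_seals=1, duration_days=50_000 / 24.0,
                        bank_attraction=0.0, heading_persistence=0.0,
                        lambda_slow=800.0, lambda_fast=4000.0, seed=2)
        (track,) = simulate_latent_tracks(cfg)
        disp = hourly_displacements(track)
        for state, lam in ((0, 800.0), (1, 4000.0)):
            mean = disp[track.states == state].mean()
            assert abs(mean - lam) / lam < 0.02

    def test_transition_frequencies_recovered(self):
        cfg = SimConfig(n_seals=1, duration_days=10_000 / 24.0, seed=3)
        (track,) = simulate_latent_tracks(cfg)
        P = np.asarray(cfg.state_transition)
        s = track.states
        for i in range(2):
            for j in range(2):
                mask = s[:-1] == i
                emp = np.mean(s[1:][mask] == j)
                assert abs(emp - P[i, j]) <= 0.02

    def test_positions_continuous(self, small_tracks):
        for trk in small_tracks:
            d = haversine_m(trk.minute_lon[:-1], trk.minute_lat[:-1],
                            trk.minute_lon[1:], trk.minute_lat[1:])
            # per-minute moves bounded by a generous hourly displacement bound
            assert d.max() < 60_000 / 60.0

    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_seals=2, duration_days=2.0, seed=9)
        t1 = simulate_latent_tracks(cfg)
        t2 = simulate_latent_tracks(cfg)
        for a, b in zip(t1, t2):
            assert (a.states == b.states).all()
            assert (a.minute_lon == b.minute_lon).all()


class TestGps:
    def test_total_failure_gives_empty_log(self, small_tracks, small_config):
        cfg = dataclasses.replace(small_config, gps_fail_prob=1.0)
        assert len(simulate_gps(small_tracks[0], cfg)) == 0

    def test_fix_count_at_15min_protocol(self):
        cfg = SimConfig(n_seals=1, duration_days=1.0, gps_fail_prob=0.0,
                        gps_interval=15, seed=1)
        (track,) = simulate_latent_tracks(cfg)
        assert len(simulate_gps(track, cfg)) == 96  # 24*60/15

    def test_degraded_fraction_binomial(self):
        cfg = SimConfig(n_seals=1, duration_days=10_000 * 5 / (24 * 60),
                        gps_interval=5, gps_fail_prob=0.0, bad_fix_prob=0.2,
                        seed=4)
        (track,) = simulate_latent_tracks(cfg)
        gps = simulate_gps(track, cfg)
        assert len(gps) >= 9_900
        degraded = (gps["n_sats"] < 5) | (gps["residual"] > 30)
        assert abs(degraded.mean() - 0.2) < 0.01

    def test_good_fixes_within_quality_bounds(self, small_tracks, small_config):
        cfg = dataclasses.replace(small_config, bad_fix_prob=0.0)
        gps = simulate_gps(small_tracks[0], cfg)
        assert (gps["n_sats"] >= 5).all() and (gps["residual"] <= 30).all()


def _stationary_pair(separation_deg_lat, duration_h=1.0):
    """Two motionless seals separated north-south by the given latitude."""
    from sealassoc.synthdata import LatentTrack
    n = int(duration_h * 60)
    mk = lambda sid, lat: LatentTrack(sid, np.zeros(int(duration_h), dtype=int),
                                      np.full(n + 1, -60.0),
                                      np.full(n + 1, lat))
    return [mk("a", 44.0), mk("b", 44.0 + separation_deg_lat)]


class TestAcoustics:
    def test_out_of_range_pair_never_detected(self):
        cfg = SimConfig(n_seals=2, duration_days=1 / 24, false_rate=0.0, seed=1)
        tracks = _stationary_pair(0.009)  # ~1 km apart, range 300 m
        assert len(simulate_acoustics(tracks, cfg)) == 0

    def test_colocated_pair_transmission_count_bounds(self):
        # 60-180 s gaps over one hour: between 20 and 60 transmissions
        cfg = SimConfig(n_seals=2, duration_days=1 / 24, false_rate=0.0,
                        pair_prob=0.0, seed=6)
        tracks = _stationary_pair(0.0)
        det = simulate_acoustics(tracks, cfg)
        for sid in ("a", "b"):
            n_tx = (det["transmitter_id"] == sid).sum()
            assert 20 <= n_tx <= 60

    def test_full_pairing_every_record_has_reciprocal(self):
        cfg = SimConfig(n_seals=2, duration_days=2 / 24, false_rate=0.0,
                        pair_prob=1.0, seed=7)
        tracks = _stationary_pair(0.0, duration_h=2.0)
        det = simulate_acoustics(tracks, cfg)
        # exhaustive matching: each record on one unit pairs with exactly one
        # record on the other unit within 180 s
        a = np.sort(det.loc[det["receiver_id"] == "a", "t"].to_numpy())
        b = np.sort(det.loc[det["receiver_id"] == "b", "t"].to_numpy())
        assert len(a) == len(b) > 0
        # optimal interval matching: earliest available partner within the
        # window (greedy on sorted endpoints is exact for this problem)
        used = np.zeros(len(b), dtype=bool)
        for t in a:
            ok = np.nonzero(~used & (np.abs(b - t) <= 180.0))[0]
            assert len(ok) > 0
            used[ok[0]] = True
        assert used.all()

    def test_no_self_detections_and_valid_flags(self, small_tracks, small_config):
        det = simulate_acoustics(small_tracks, small_config)
        assert (det["receiver_id"] != det["transmitter_id"]).all()
        true_det = det[det["valid"] == 1]
        # step model: every true detection occurred within detection range
        by_id = {t.seal_id: t for t in small_tracks}
        for row in true_det.sample(min(len(true_det), 300),
                                   random_state=0).itertuples(index=False):
            # reciprocal records are delayed copies; allow one cycle of motion
            lon_r, lat_r = by_id[row.receiver_id].position_at(row.t)
            lon_t, lat_t = by_id[row.transmitter_id].position_at(row.t)
            d = haversine_m(lon_r, lat_r, lon_t, lat_t)
            assert d <= small_config.detection_range + 2 * 170.0 * 2.0

    def test_duplicate_ids_rejected(self, small_tracks, small_config):
        with pytest.raises(ValueError):
            simulate_acoustics([small_tracks[0], small_tracks[0]], small_config)


class TestBathymetry:
    def test_depth_shallow_at_banks_deep_far_away(self, small_config):
        raster = simulate_bathymetry(small_config)
        for bx, by in small_config.bank_centres:
            assert depth_at(raster, bx, by) <= 60.0
        x0, x1, y0, y1 = raster.extent
        assert depth_at(raster, x0 + raster.cellsize, y0 + raster.cellsize) >= 150.0

    def test_roundtrip_is_exact(self, small_config, tmp_path):
        raster = simulate_bathymetry(small_config, cellsize_min=2.0)
        path = tmp_path / "b.asc"
        from sealassoc.ascii_grid import write_ascii_grid
        write_ascii_grid(raster, path)
        back = read_ascii_grid(path)
        assert (back.values == raster.values).all()
        assert back.cellsize == raster.cellsize

    def test_extent_must_cover_banks(self, small_config):
        with pytest.raises(ValueError):
            simulate_bathymetry(small_config, cellsize_min=2.0,
                                extent=(-59.0, -58.0, 44.0, 45.0))


class TestScenario:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimConfig(n_seals=2, duration_days=1.0, seed=21)
        d1, d2 = tmp_path / "s1", tmp_path / "s2"
        m1 = make_scenario(cfg, d1)
        make_scenario(cfg, d2)
        names = (m1.gps_files + m1.detection_files
                 + [m1.bathymetry_file, m1.truth_states_file,
                    m1.truth_proximity_file, "manifest.json"])
        match, mismatch, errors = filecmp.cmpfiles(d1, d2, names, shallow=False)
        assert not mismatch and not errors and len(match) == len(names)

    def test_manifest_enumerates_all_files(self, small_scenario_dir,
                                           small_config):
        import json
        man = json.loads((small_scenario_dir / "manifest.json").read_text())
        assert len(man["gps_files"]) == small_config.n_seals
        assert len(man["detection_files"]) == small_config.n_seals
        assert (small_scenario_dir / man["bathymetry_file"]).exists()

    def test_colocated_pair_yields_truth_intervals(self):
        tracks = _stationary_pair(0.0, duration_h=2.0)
        prox = true_proximity_intervals(tracks, 300.0)
        assert len(prox) == 1
        assert prox.loc[0, "start"] == 0.0
        assert prox.loc[0, "end"] == pytest.approx(2 * 3600.0, abs=60.0)
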