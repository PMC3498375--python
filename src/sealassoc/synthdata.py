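"""Synthetic biologging deployments with known ground truth.

Emulates a fall foraging deployment of grey seals carrying a 69 kHz acoustic
transceiver (transmit-and-listen proximity logger) and an archival Fastloc
GPS tag:

* latent movement: a two-state (slow/fast) Markov chain over hours with
  exponential hourly step lengths (mean ``lambda_state`` metres), persistent
  headings, and optional attraction toward shallow offshore bank centres;
* GPS logs: fixes on a 5- or 15-min schedule with dropout, isotropic
  position noise, and a fraction of degraded fixes (few satellites or large
  residual error);
* acoustic logs: irregular transmissions every 60–180 s, detected by any
  other animal within ~300 m, with reciprocal paired records on the
  transmitting unit in 97% of cases, plus rare false detections;
* bathymetry: a smooth deep field with Gaussian shallowing at bank centres,
  written as an ESRI ASCII grid.

Every simulated quantity that downstream stages estimate (latent states,
true positions, true proximity intervals) is retained, so recovery can be
measured exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ascii_grid import BathymetryRaster, write_ascii_grid
from .geo import haversine_m, step_lonlat, bearing_rad
from .timebase import to_iso

log = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "LatentTrack",
    "simulate_latent_tracks",
    "simulate_gps",
    "simulate_acoustics",
    "simulate_bathymetry",
    "true_proximity_intervals",
    "make_scenario",
]

SLOW, FAST = 0, 1
STATE_NAMES = ("slow", "fast")


@dataclass
class SimConfig:
    """Deployment scenario parameters.

    Defaults describe the study conditions this generator emulates: 13
    animals tracked for ~79 days, 15-min GPS schedule, 60–180 s transmission
    gaps, ~300 m detection range, 97% reciprocal records, rare false
    detections.
    """

    n_seals: int = 13
    duration_days: float = 79.0
    #: hourly state transition matrix, rows (slow, fast)
    state_transition: tuple = ((0.9, 0.1), (0.2, 0.8))
    lambda_slow: float = 800.0     # mean hourly displacement, m (ARS-like)
    lambda_fast: float = 4000.0    # mean hourly displacement, m (transit)
    heading_persistence: float = 0.8
    bank_centres: tuple = ((-60.6, 44.45), (-59.4, 44.15))
    bank_attraction: float = 1.0
    origin: tuple = (-60.0, 43.93)   # colony; seals start scattered nearby
    origin_scatter_m: float = 2000.0
    gps_interval: int = 15           # minutes, 5 or 15
    gps_fail_prob: float = 0.075
    bad_fix_prob: float = 0.05
    gps_noise_sd: float = 25.0       # m, isotropic
    tx_gap_min: float = 60.0         # s
    tx_gap_max: float = 180.0        # s
    detection_range: float = 300.0   # m
    detection_model: str = "step"    # or "logistic"
    logistic_scale: float = 50.0     # m, for the logistic model
    pair_prob: float = 0.97
    false_rate: float = 0.025        # false detections per receiver-day
    n_males: int = 5                 # remaining seals are female
    seed: int = 0

    def validate(self) -> None:
        P = np.asarray(self.state_transition, dtype=float)
        if P.shape != (2, 2) or np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("state_transition must be a 2x2 row-stochastic matrix")
        if self.lambda_slow <= 0 or self.lambda_fast <= 0:
            raise ValueError("emission means must be positive")
        if not self.lambda_slow < self.lambda_fast:
            raise ValueError("lambda_slow must be < lambda_fast")
        if not 0 <= self.heading_persistence <= 1:
            raise ValueError("heading_persistence must be in [0, 1]")
        if self.bank_attraction < 0:
            raise ValueError("bank_attraction must be >= 0")
        if not self.tx_gap_min < self.tx_gap_max:
            raise ValueError("tx_gap_min must be < tx_gap_max")
        for name in ("gps_fail_prob", "bad_fix_prob", "pair_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.gps_interval not in (5, 15):
            raise ValueError("gps_interval must be 5 or 15 minutes")
        if self.n_seals < 0:
            raise ValueError("n_seals must be >= 0")
        if self.detection_model not in ("step", "logistic"):
            raise ValueError("detection_model must be 'step' or 'logistic'")

    @property
    def seal_ids(self) -> list[str]:
        return [f"seal{i:02d}" for i in range(self.n_seals)]

    @property
    def sexes(self) -> dict[str, str]:
        return {sid: ("M" if i < self.n_males else "F")
                for i, sid in enumerate(self.seal_ids)}

    @property
    def n_hours(self) -> int:
        return int(round(self.duration_days * 24))


@dataclass
class LatentTrack:
    """Ground-truth movement of one animal.

    ``states[h]`` is the latent state for hour h; positions are stored at
    1-min resolution (``minute_lon[k]`` at t = 60*k seconds).
    """

    seal_id: str
    states: np.ndarray       # (n_hours,) int, 0=slow 1=fast
    minute_lon: np.ndarray   # (n_hours*60 + 1,)
    minute_lat: np.ndarray

    @property
    def duration_s(self) -> float:
        return 60.0 * (len(self.minute_lon) - 1)

    def position_at(self, t):
        """True position at time(s) ``t`` seconds, linear between minutes."""
        t = np.asarray(t, dtype=float)
        k = np.clip(t / 60.0, 0.0, len(self.minute_lon) - 1.0)
        idx = np.arange(len(self.minute_lon), dtype=float)
        return np.interp(k, idx, self.minute_lon), np.interp(k, idx, self.minute_lat)


def _seal_rng(config: SimConfig, stream: int, index: int) -> np.random.Generator:
    # independent, reproducible stream per (purpose, seal)
    return np.random.default_rng([config.seed, stream, index])


def simulate_latent_tracks(config: SimConfig) -> list[LatentTrack]:
    """Draw latent state sequences and continuous positions for every seal.

    Hourly step lengths are Exponential(lambda_state); headings follow the
    previous heading perturbed by wrapped-normal noise with sd
    ``(1 - heading_persistence) * pi``, then biased toward the nearest bank
    centre with weight ``bank_attraction``.  Positions are linear within the
    hour, so the displacement over any whole hour equals the drawn step.
    """
    config.validate()
    P = np.asarray(config.state_transition, dtype=float)
    lam = np.array([config.lambda_slow, config.lambda_fast])
    banks = np.asarray(config.bank_centres, dtype=float).reshape(-1, 2)
    n_hours = config.n_hours
    tracks: list[LatentTrack] = []

    # stationary distribution of the hourly chain for the initial state
    evals, evecs = np.linalg.eig(P.T)
    pi0 = np.real(evecs[:, np.argmax(np.real(evals))])
    pi0 = np.abs(pi0) / np.abs(pi0).sum()

    for i, sid in enumerate(config.seal_ids):
        rng = _seal_rng(config, 1, i)
        states = np.empty(n_hours, dtype=int)
        s = rng.choice(2, p=pi0)
        for h in range(n_hours):
            states[h] = s
            s = rng.choice(2, p=P[s])

        steps = rng.exponential(lam[states])
        noise_sd = (1.0 - config.heading_persistence) * np.pi
        theta = rng.uniform(0.0, 2.0 * np.pi)
        jitter = np.degrees(config.origin_scatter_m / 6_371_008.8)
        lon = config.origin[0] + rng.normal(0.0, jitter)
        lat = config.origin[1] + rng.normal(0.0, jitter)

        node_lon = np.empty(n_hours + 1)
        node_lat = np.empty(n_hours + 1)
        node_lon[0], node_lat[0] = lon, lat
        for h in range(n_hours):
            theta = theta + rng.normal(0.0, noise_sd)
            if config.bank_attraction > 0 and len(banks):
                d = haversine_m(lon, lat, banks[:, 0], banks[:, 1])
                b = banks[int(np.argmin(d))]
                beta = bearing_rad(lon, lat, b[0], b[1])
                vx = np.sin(theta) + config.bank_attraction * np.sin(beta)
                vy = np.cos(theta) + config.bank_attraction * np.cos(beta)
                theta = float(np.arctan2(vx, vy))
            lon, lat = step_lonlat(lon, lat, steps[h], theta)
            node_lon[h + 1], node_lat[h + 1] = lon, lat

        # minute-resolution positions, linear within each hour
        frac = np.arange(60) / 60.0
        mlon = (node_lon[:-1, None] * (1 - frac) + node_lon[1:, None] * frac).ravel()
        mlat = (node_lat[:-1, None] * (1 - frac) + node_lat[1:, None] * frac).ravel()
        mlon = np.append(mlon, node_lon[-1])
        mlat = np.append(mlat, node_lat[-1])
        tracks.append(LatentTrack(sid, states, mlon, mlat))
    return tracks


def simulate_gps(track: LatentTrack, config: SimConfig) -> pd.DataFrame:
    """Archival GPS log for one animal.

    Columns: ``seal_id, t, lon, lat, n_sats, residual``.  Fixes on the
    configured schedule are dropped independently with ``gps_fail_prob``;
    a ``bad_fix_prob`` fraction is degraded (satellites in {3,4} or residual
    error > 30); positions get isotropic noise (sd ``gps_noise_sd`` m).
    """
    config.validate()
    idx = config.seal_ids.index(track.seal_id) if track.seal_id in config.seal_ids else 0
    rng = _seal_rng(config, 2, idx)
    times = np.arange(0.0, track.duration_s, config.gps_interval * 60.0)
    keep = rng.random(len(times)) >= config.gps_fail_prob
    times = times[keep]
    lon, lat = track.position_at(times)
    dn = rng.normal(0.0, config.gps_noise_sd, len(times))
    de = rng.normal(0.0, config.gps_noise_sd, len(times))
    lat = lat + np.degrees(dn / 6_371_008.8)
    lon = lon + np.degrees(de / (6_371_008.8 * np.cos(np.radians(lat))))

    n_sats = rng.integers(5, 13, len(times))
    residual = rng.uniform(0.0, 30.0, len(times))
    bad = rng.random(len(times)) < config.bad_fix_prob
    bad_mode = rng.random(len(times)) < 0.5  # True -> few satellites
    few = bad & bad_mode
    n_sats[few] = rng.integers(3, 5, int(few.sum()))
    high = bad & ~bad_mode
    residual[high] = rng.uniform(31.0, 100.0, int(high.sum()))

    return pd.DataFrame({
        "seal_id": track.seal_id,
        "t": times,
        "lon": lon,
        "lat": lat,
        "n_sats": n_sats,
        "residual": residual,
    })


def _detect_mask(dist: np.ndarray, config: SimConfig,
                 rng: np.random.Generator) -> np.ndarray:
    if config.detection_model == "step":
        return dist <= config.detection_range
    p = 1.0 / (1.0 + np.exp((dist - config.detection_range) / config.logistic_scale))
    return rng.random(len(dist)) < p


def simulate_acoustics(tracks: list[LatentTrack], config: SimConfig) -> pd.DataFrame:
    """Pooled acoustic detection log for the whole fleet.

    Columns: ``receiver_id, t, transmitter_id, valid``.  Each transmission
    by A heard by B yields a record on B's log; with probability
    ``pair_prob`` a reciprocal record appears on A's log within one
    transmission cycle.  Self-detections never occur (the transceiver blanks
    its receiver while transmitting).  False detections are a Poisson
    process per receiver with ``false_rate`` per day, flagged invalid.
    """
    config.validate()
    ids = [t.seal_id for t in tracks]
    if len(set(ids)) != len(ids):
        raise ValueError("overlapping seal IDs in tracks")

    recs: list[pd.DataFrame] = []
    for i, trk in enumerate(tracks):
        rng = _seal_rng(config, 3, i)
        gaps = rng.uniform(config.tx_gap_min, config.tx_gap_max,
                           int(trk.duration_s / config.tx_gap_min) + 2)
        tx = rng.uniform(0.0, config.tx_gap_max) + np.cumsum(gaps)
        tx = tx[tx < trk.duration_s]
        lon_a, lat_a = trk.position_at(tx)
        for j, other in enumerate(tracks):
            if j == i:
                continue
            lon_b, lat_b = other.position_at(tx)
            dist = haversine_m(lon_a, lat_a, lon_b, lat_b)
            heard = _detect_mask(dist, config, rng)
            t_heard = tx[heard]
            if len(t_heard) == 0:
                continue
            recs.append(pd.DataFrame({
                "receiver_id": other.seal_id,
                "t": t_heard,
                "transmitter_id": trk.seal_id,
                "valid": 1,
            }))
            # the same transmission is logged on both units almost
            # simultaneously; the offset models seconds-scale clock drift
            paired = rng.random(len(t_heard)) < config.pair_prob
            if paired.any():
                delay = rng.uniform(0.0, 10.0, int(paired.sum()))
                recs.append(pd.DataFrame({
                    "receiver_id": trk.seal_id,
                    "t": t_heard[paired] + delay,
                    "transmitter_id": other.seal_id,
                    "valid": 1,
                }))

    # false detections: random transmitter from the fleet, invalid flag
    if config.false_rate > 0 and len(tracks) > 1:
        for i, trk in enumerate(tracks):
            rng = _seal_rng(config, 4, i)
            n_false = rng.poisson(config.false_rate * trk.duration_s / 86400.0)
            if n_false == 0:
                continue
            others = [s for s in ids if s != trk.seal_id]
            recs.append(pd.DataFrame({
                "receiver_id": trk.seal_id,
                "t": rng.uniform(0.0, trk.duration_s, n_false),
                "transmitter_id": rng.choice(others, n_false),
                "valid": 0,
            }))

    if not recs:
        return pd.DataFrame(columns=["receiver_id", "t", "transmitter_id", "valid"])
    out = pd.concat(recs, ignore_index=True)
    return (out.sort_values(["receiver_id", "t", "transmitter_id"])
               .reset_index(drop=True))


def simulate_bathymetry(config: SimConfig, cellsize_min: float = 0.25,
                        base_depth: float = 200.0, bank_depth: float = 50.0,
                        bank_sigma_m: float = 15_000.0, pad_deg: float = 1.0,
                        extent: tuple | None = None) -> BathymetryRaster:
    """Smooth synthetic depth field: deep baseline with Gaussian shallowing
    at each bank centre (to ``bank_depth`` m at the centre).

    By default the extent covers all bank centres and the colony padded by
    ``pad_deg`` degrees; an explicit ``extent`` (lon_min, lon_max, lat_min,
    lat_max) must still cover every bank centre or it is rejected.  Cell
    size defaults to 0.25 arc-minutes.
    """
    config.validate()
    pts = np.asarray(list(config.bank_centres) + [config.origin], dtype=float)
    if len(pts) == 0:
        raise ValueError("no bank centres or origin to cover")
    cs = cellsize_min / 60.0
    if extent is not None:
        xll, xur, yll, yur = (float(v) for v in extent)
    else:
        xll = float(pts[:, 0].min() - pad_deg)
        yll = float(pts[:, 1].min() - pad_deg)
        xur = float(pts[:, 0].max() + pad_deg)
        yur = float(pts[:, 1].max() + pad_deg)
    ncols = int(np.ceil((xur - xll) / cs))
    nrows = int(np.ceil((yur - yll) / cs))

    lon_c = xll + (np.arange(ncols) + 0.5) * cs
    lat_c = yll + (nrows - 1 - np.arange(nrows) + 0.5) * cs  # north first
    LON, LAT = np.meshgrid(lon_c, lat_c)
    depth = np.full(LON.shape, base_depth)
    for bx, by in np.asarray(config.bank_centres, dtype=float).reshape(-1, 2):
        if not (xll <= bx <= xur and yll <= by <= yur):
            raise ValueError("raster extent excludes a bank centre")
        d = haversine_m(LON, LAT, bx, by)
        depth -= (base_depth - bank_depth) * np.exp(-0.5 * (d / bank_sigma_m) ** 2)
    depth = np.clip(depth, 20.0, None)
    return BathymetryRaster(values=depth, xllcorner=xll, yllcorner=yll, cellsize=cs)


def true_proximity_intervals(tracks: list[LatentTrack],
                             range_m: float) -> pd.DataFrame:
    """Maximal intervals (1-min resolution) during which a dyad's true
    separation is <= ``range_m``.

    Columns: ``seal_a, seal_b, start, end`` (seconds; end inclusive at the
    last in-range minute).
    """
    rows = []
    for i in range(len(tracks)):
        for j in range(i + 1, len(tracks)):
            a, b = tracks[i], tracks[j]
            n = min(len(a.minute_lon), len(b.minute_lon))
            d = haversine_m(a.minute_lon[:n], a.minute_lat[:n],
                            b.minute_lon[:n], b.minute_lat[:n])
            close = d <= range_m
            if not close.any():
                continue
            edges = np.diff(close.astype(int))
            starts = list(np.where(edges == 1)[0] + 1)
            ends = list(np.where(edges == -1)[0])
            if close[0]:
                starts = [0] + starts
            if close[-1]:
                ends = ends + [n - 1]
            for s, e in zip(starts, ends):
                rows.append((a.seal_id, b.seal_id, 60.0 * s, 60.0 * e))
    return pd.DataFrame(rows, columns=["seal_a", "seal_b", "start", "end"])


@dataclass
class ScenarioManifest:
    seed: int
    gps_files: list[str] = field(default_factory=list)
    detection_files: list[str] = field(default_factory=list)
    bathymetry_file: str = ""
    truth_states_file: str = ""
    truth_proximity_file: str = ""
    sexes_file: str = ""


def _write_gps_log(df: pd.DataFrame, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("seal_id,timestamp,lon,lat,n_sats,residual\n")
        for row in df.itertuples(index=False):
            fh.write(f"{row.seal_id},{to_iso(row.t)},{row.lon!r},{row.lat!r},"
                     f"{int(row.n_sats)},{row.residual!r}\n")


def _write_detection_log(df: pd.DataFrame, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("receiver_id,timestamp,transmitter_id,valid\n")
        for row in df.itertuples(index=False):
            fh.write(f"{row.receiver_id},{to_iso(row.t)},{row.transmitter_id},"
                     f"{int(row.valid)}\n")


def make_scenario(config: SimConfig, outdir) -> ScenarioManifest:
    """Simulate a full deployment and write all artefacts to ``outdir``.

    Writes one GPS log and one detection log per seal, the bathymetry grid,
    ground-truth latent states and dyad proximity intervals, a seal-sex
    table, and ``manifest.json``.  Output is byte-identical for identical
    configs (same seed).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = ScenarioManifest(seed=config.seed)

    tracks = simulate_latent_tracks(config)
    detections = simulate_acoustics(tracks, config) if len(tracks) >= 2 else \
        pd.DataFrame(columns=["receiver_id", "t", "transmitter_id", "valid"])

    for trk in tracks:
        gps = simulate_gps(trk, config)
        gp = outdir / f"gps_{trk.seal_id}.csv"
        _write_gps_log(gps, gp)
        manifest.gps_files.append(gp.name)
        dp = outdir / f"detections_{trk.seal_id}.csv"
        sub = detections[detections["receiver_id"] == trk.seal_id]
        _write_detection_log(sub, dp)
        manifest.detection_files.append(dp.name)

    raster = simulate_bathymetry(config)
    bp = outdir / "bathymetry.asc"
    write_ascii_grid(raster, bp)
    manifest.bathymetry_file = bp.name

    sp = outdir / "truth_states.csv"
    with sp.open("w") as fh:
        fh.write("seal_id,hour,state\n")
        for trk in tracks:
            for h, s in enumerate(trk.states):
                fh.write(f"{trk.seal_id},{h},{STATE_NAMES[s]}\n")
    manifest.truth_states_file = sp.name

    prox = true_proximity_intervals(tracks, config.detection_range)
    pp = outdir / "truth_proximity.csv"
    with pp.open("w") as fh:
        fh.write("seal_a,seal_b,start_iso,end_iso\n")
        for row in prox.itertuples(index=False):
            fh.write(f"{row.seal_a},{row.seal_b},{to_iso(row.start)},{to_iso(row.end)}\n")
    manifest.truth_proximity_file = pp.name

    xp = outdir / "sexes.csv"
    with xp.open("w") as fh:
        fh.write("seal_id,sex\n")
        for sid, sex in config.sexes.items():
            fh.write(f"{sid},{sex}\n")
    manifest.sexes_file = xp.name

    with (outdir / "manifest.json").open("w") as fh:
        json.dump({"config": asdict(config), **asdict(manifest)},
                  fh, indent=2, sort_keys=True, default=list)
        fh.write("\n")
    log.info("scenario written to %s (%d seals, %d detections)",
             outdir, len(tracks), len(detections))
    return manifest
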