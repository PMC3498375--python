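"""Detection-log cleaning and gap-rule dyadic association clustering.

A proximity logger on animal B records the unique code of animal A whenever
A transmits within range.  In most cases the transmitting unit also logs a
matching reciprocal record, so a true detection is counted once per pair.
An *association* between two animals is a maximal run of detection events
in which no inter-event gap exceeds 30 minutes; a gap of more than 30
minutes ends the association.  Single-detection associations are assigned a
nominal 3-minute duration (after which another detection would have been
logged had the pair still been together, given the 60–180 s transmission
schedule).  Association locations are estimated by linear interpolation of
each animal's GPS track.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .geo import haversine_m
from .timebase import from_iso

log = logging.getLogger(__name__)

__all__ = [
    "read_detection_log",
    "filter_false_detections",
    "pair_events",
    "cluster_associations",
    "locate_associations",
    "event_separations",
]

DETECTION_COLUMNS = ["receiver_id", "t", "transmitter_id", "valid"]


def read_detection_log(path) -> pd.DataFrame:
    """Parse a detection log (``receiver_id,timestamp,transmitter_id,valid``).

    Returns a DataFrame with columns ``receiver_id, t, transmitter_id,
    valid`` sorted chronologically per receiver.  Lines with unparseable
    timestamps are skipped and counted (``df.attrs['n_skipped']``, also
    logged); missing columns are a hard error.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip().split(",")
        required = ["receiver_id", "timestamp", "transmitter_id", "valid"]
        if [h.strip() for h in header] != required:
            raise ValueError(f"{path}: expected header {','.join(required)!r}, "
                             f"got {','.join(header)!r}")
        rows, n_skipped = [], 0
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 4:
                n_skipped += 1
                log.warning("%s:%d: malformed line skipped", path, lineno)
                continue
            try:
                t = from_iso(parts[1])
                valid = int(parts[3])
            except (ValueError, OverflowError):
                n_skipped += 1
                log.warning("%s:%d: unparseable record skipped", path, lineno)
                continue
            rows.append((parts[0], t, parts[2], valid))
    df = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    df = df.sort_values(["receiver_id", "t"]).reset_index(drop=True)
    df.attrs["n_skipped"] = n_skipped
    if n_skipped:
        log.info("%s: skipped %d malformed line(s)", path, n_skipped)
    return df


def filter_false_detections(records: pd.DataFrame, heuristic: bool = False,
                            isolation_window_s: float = 3600.0
                            ) -> tuple[pd.DataFrame, int]:
    """Remove false detections; returns ``(kept, removed_count)``.

    Records flagged invalid (``valid == 0``) are removed.  With
    ``heuristic=True`` an additional isolation rule also removes records of
    a transmitter with no second record on the same receiver within
    +/- ``isolation_window_s`` (off by default).
    """
    keep = records["valid"].astype(int) != 0
    if heuristic:
        iso = np.zeros(len(records), dtype=bool)
        for _, grp in records.groupby(["receiver_id", "transmitter_id"], sort=False):
            t = grp["t"].to_numpy()
            order = np.argsort(t)
            ts = t[order]
            gap_prev = np.diff(ts, prepend=-np.inf)
            gap_next = np.diff(ts, append=np.inf)
            isolated = (gap_prev > isolation_window_s) & (gap_next > isolation_window_s)
            iso[grp.index.to_numpy()[order]] = isolated
        keep &= ~iso
    kept = records[keep].reset_index(drop=True)
    removed = int(len(records) - len(kept))
    return kept, removed


def _dyad_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def pair_events(records: pd.DataFrame, tolerance: float = 180.0) -> pd.DataFrame:
    """Collapse reciprocal record pairs into single detection events.

    For each dyad, records on the first seal's log referencing the second
    are matched greedily, in chronological order, to the nearest unmatched
    reciprocal record within ``+/- tolerance`` seconds.  Each matched pair
    yields one two-way event at the earlier of the two timestamps; unmatched
    records become one-way events.  The result is invariant to which
    animal's log a record sits on (the driving side is the lexicographically
    smaller ID).

    Returns columns ``seal_a, seal_b, t, two_way`` sorted by dyad then time.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    events = []
    if len(records):
        dyads = {}
        for row in records.itertuples(index=False):
            dyads.setdefault(_dyad_key(row.receiver_id, row.transmitter_id),
                             ([], []))
        for row in records.itertuples(index=False):
            a, b = _dyad_key(row.receiver_id, row.transmitter_id)
            side = 0 if row.receiver_id == a else 1
            dyads[(a, b)][side].append(row.t)
        for (a, b), (ta, tb) in dyads.items():
            ta = np.sort(np.asarray(ta))
            tb = np.sort(np.asarray(tb))
            matched_b = np.zeros(len(tb), dtype=bool)
            for t in ta:
                # nearest unmatched reciprocal within tolerance
                lo = np.searchsorted(tb, t - tolerance, side="left")
                hi = np.searchsorted(tb, t + tolerance, side="right")
                cand = [k for k in range(lo, hi) if not matched_b[k]]
                if cand:
                    k = min(cand, key=lambda k: (abs(tb[k] - t), tb[k]))
                    matched_b[k] = True
                    events.append((a, b, min(t, tb[k]), True))
                else:
                    events.append((a, b, t, False))
            for k in np.nonzero(~matched_b)[0]:
                events.append((a, b, tb[k], False))
    df = pd.DataFrame(events, columns=["seal_a", "seal_b", "t", "two_way"])
    return df.sort_values(["seal_a", "seal_b", "t"]).reset_index(drop=True)


def cluster_associations(events: pd.DataFrame, gap_threshold_min: float = 30.0,
                         singleton_duration_min: float = 3.0) -> pd.DataFrame:
    """Split each dyad's event stream into associations by the gap rule.

    Consecutive events stay in the same association while the gap is
    <= ``gap_threshold_min`` (a gap strictly greater than the threshold
    starts a new association; a gap of exactly the threshold does not).
    Duration is last-minus-first event time; single-event associations get
    ``singleton_duration_min``.

    Returns one row per association: ``assoc_id, seal_a, seal_b, start, end,
    n_events, duration_h``.  The input ``events`` gains an ``assoc_id``
    column mapping every event to its association.
    """
    if gap_threshold_min <= 0:
        raise ValueError("gap_threshold must be positive")
    if len(events) == 0:
        events["assoc_id"] = pd.Series(dtype=int)
        return pd.DataFrame(columns=["assoc_id", "seal_a", "seal_b", "start",
                                     "end", "n_events", "duration_h"])
    ev = events.sort_values(["seal_a", "seal_b", "t"])
    gap_s = gap_threshold_min * 60.0
    new_dyad = ((ev["seal_a"] != ev["seal_a"].shift())
                | (ev["seal_b"] != ev["seal_b"].shift()))
    new_run = new_dyad | (ev["t"].diff() > gap_s)
    assoc_id = new_run.cumsum().astype(int) - 1
    events.loc[ev.index, "assoc_id"] = assoc_id.to_numpy()
    events["assoc_id"] = events["assoc_id"].astype(int)

    grouped = ev.assign(assoc_id=assoc_id.to_numpy()).groupby("assoc_id")
    out = grouped.agg(seal_a=("seal_a", "first"), seal_b=("seal_b", "first"),
                      start=("t", "min"), end=("t", "max"),
                      n_events=("t", "size")).reset_index()
    out["duration_h"] = (out["end"] - out["start"]) / 3600.0
    out.loc[out["n_events"] == 1, "duration_h"] = singleton_duration_min / 60.0
    return out


def _interp_track(gps: pd.DataFrame, t):
    """Linear component-wise interpolation of one seal's fixes at times t.
    NaN outside the fix range (needs a bracketing fix on each side)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    g = gps.sort_values("t")
    tt = g["t"].to_numpy()
    if len(tt) == 0:
        return np.full(len(t), np.nan), np.full(len(t), np.nan)
    lon = np.interp(t, tt, g["lon"].to_numpy())
    lat = np.interp(t, tt, g["lat"].to_numpy())
    outside = (t < tt[0]) | (t > tt[-1])
    lon[outside] = np.nan
    lat[outside] = np.nan
    return lon, lat


def locate_associations(associations: pd.DataFrame, events: pd.DataFrame,
                        gps_by_seal: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Attach interpolated locations and separations to associations.

    Each seal's position is interpolated at the association's midpoint time;
    ``separation_km`` is the haversine distance between the two interpolated
    points, and ``median_separation_km`` the median over the association's
    per-event separations.  A seal whose fixes do not bracket the midpoint
    gets a missing location (the association is retained, with a logged
    warning).
    """
    out = associations.copy()
    for col in ("lon_a", "lat_a", "lon_b", "lat_b",
                "separation_km", "median_separation_km"):
        out[col] = np.nan
    ev_sep = events.copy()
    ev_sep["separation_km"] = event_separations(events, gps_by_seal)
    n_missing = 0
    for i, row in out.iterrows():
        mid = 0.5 * (row["start"] + row["end"])
        pos = {}
        for which, sid in (("a", row["seal_a"]), ("b", row["seal_b"])):
            gps = gps_by_seal.get(sid)
            if gps is None or len(gps) == 0:
                n_missing += 1
                continue
            lon, lat = _interp_track(gps, mid)
            if np.isnan(lon[0]):
                n_missing += 1
                continue
            out.loc[i, f"lon_{which}"] = lon[0]
            out.loc[i, f"lat_{which}"] = lat[0]
            pos[which] = (lon[0], lat[0])
        if len(pos) == 2:
            out.loc[i, "separation_km"] = haversine_m(*pos["a"], *pos["b"]) / 1000.0
        if "assoc_id" in ev_sep.columns:
            seps = ev_sep.loc[ev_sep["assoc_id"] == row["assoc_id"], "separation_km"]
            if seps.notna().any():
                out.loc[i, "median_separation_km"] = float(seps.median())
    if n_missing:
        log.warning("locate_associations: %d seal location(s) missing "
                    "(midpoint outside GPS fix range)", n_missing)
    return out


def event_separations(events: pd.DataFrame,
                      gps_by_seal: dict[str, pd.DataFrame]) -> np.ndarray:
    """Inter-seal separation (km) at each detection event time.

    Both seals' positions are interpolated at the event time; NaN where a
    seal's fixes do not bracket it.
    """
    sep = np.full(len(events), np.nan)
    if len(events) == 0:
        return sep
    for (a, b), grp in events.groupby(["seal_a", "seal_b"], sort=False):
        ga, gb = gps_by_seal.get(a), gps_by_seal.get(b)
        if ga is None or gb is None:
            continue
        t = grp["t"].to_numpy()
        lon_a, lat_a = _interp_track(ga, t)
        lon_b, lat_b = _interp_track(gb, t)
        sep[grp.index.to_numpy()] = haversine_m(lon_a, lat_a, lon_b, lat_b) / 1000.0
    return sep
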