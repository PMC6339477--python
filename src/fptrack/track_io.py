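"""Reading, validation, regularisation and speed-filtering of GPS tracks.

A *track* is one foraging trip of one individual: an ordered series of GPS
fixes (timestamp, longitude, latitude in decimal degrees WGS84).  Loggers in
the field record at heterogeneous rates, so tracks are first thinned to a
common nominal interval (1 fix/min by default) by greedy nearest-to-grid
subsampling — no positional interpolation, which would fabricate locations
that the first-passage-time analysis downstream would then treat as real.
Fixes reached at ground speed below 10 km/h indicate a bird sitting on the
water and are flagged for removal from behavioural analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import RowParseError, SchemaError

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0

#: default column mapping for :func:`read_tracks`
DEFAULT_SCHEMA = {
    "individual_id": "individual_id",
    "trip_id": "trip_id",
    "timestamp": "timestamp",
    "lon": "lon",
    "lat": "lat",
}


@dataclass
class Track:
    """Ordered fixes of one individual trip.

    ``fixes`` holds columns ``timestamp`` (UTC), ``lon``, ``lat``; timestamps
    are strictly increasing.
    """

    individual_id: str
    trip_id: str
    fixes: pd.DataFrame

    def __post_init__(self):
        ts = self.fixes["timestamp"]
        if len(self.fixes) < 2:
            raise ValueError(f"track {self.trip_id}: needs >= 2 fixes")
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError(f"track {self.trip_id}: timestamps not strictly increasing")

    def __len__(self) -> int:
        return len(self.fixes)


@dataclass
class RegularisedTrack:
    """A track thinned to a near-regular time grid.

    Additional per-fix columns: ``speed_ms`` (incoming-segment ground speed,
    NaN for the first fix of each segment), ``sitting`` (bool), and
    ``segment_id`` (increments across gaps longer than twice the nominal
    interval; first-passage accumulation never crosses a segment boundary).
    """

    individual_id: str
    trip_id: str
    fixes: pd.DataFrame
    nominal_interval_s: float
    usable: bool = True
    #: speeds recomputed over the retained (non-sitting) sequence, aligned to
    #: retained fixes; populated by :func:`flag_sitting`
    retained_speeds_ms: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.fixes)

    def retained(self) -> pd.DataFrame:
        """Fixes that survive the sitting filter."""
        return self.fixes.loc[~self.fixes["sitting"]]


def haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance in metres on a sphere of radius 6,371,000 m.

    Accepts scalars or arrays (broadcast).  Symmetric and non-negative.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


def _validate_coords(lon: pd.Series, lat: pd.Series) -> np.ndarray:
    """Boolean mask of rows with invalid or unparseable coordinates."""
    bad = (
        ~np.isfinite(lon)
        | ~np.isfinite(lat)
        | (np.abs(lat) > 90.0)
        | (np.abs(lon) > 180.0)
    )
    return np.asarray(bad)


def read_tracks(path, schema: dict[str, str] | None = None, sep: str = ",") -> list[Track]:
    """Read delimited-text fixes into one :class:`Track` per (individual, trip).

    ``schema`` maps the logical names ``individual_id``, ``timestamp``,
    ``lon``, ``lat`` (and optionally ``trip_id``) to column names in the file.
    Rows are sorted by time within trip; duplicate timestamps collapse to the
    first occurrence with a logged warning.  Unparseable timestamps or
    out-of-range coordinates raise :class:`RowParseError` listing the 1-based
    data line numbers.  An empty file yields an empty list.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    raw = pd.read_csv(path, sep=sep)
    if raw.empty:
        return []
    required = ["individual_id", "timestamp", "lon", "lat"]
    missing = [schema[k] for k in required if schema[k] not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    df = pd.DataFrame(
        {
            "individual_id": raw[schema["individual_id"]].astype(str),
            "timestamp": pd.to_datetime(raw[schema["timestamp"]], utc=True, errors="coerce"),
            "lon": pd.to_numeric(raw[schema["lon"]], errors="coerce"),
            "lat": pd.to_numeric(raw[schema["lat"]], errors="coerce"),
        }
    )
    trip_col = schema.get("trip_id")
    if trip_col and trip_col in raw.columns:
        df["trip_id"] = raw[trip_col].astype(str)
    else:
        df["trip_id"] = df["individual_id"]

    bad = df["timestamp"].isna().to_numpy() | _validate_coords(df["lon"], df["lat"])
    if bad.any():
        # +2: header line plus 1-based indexing
        lines = (np.nonzero(bad)[0] + 2).tolist()
        raise RowParseError("unparseable timestamp or out-of-range coordinate", lines)

    tracks: list[Track] = []
    for (ind, trip), g in df.groupby(["individual_id", "trip_id"], sort=True):
        if not g["timestamp"].is_monotonic_increasing:
            logger.warning("trip %s/%s: rows out of time order, re-sorting", ind, trip)
            g = g.sort_values("timestamp", kind="stable")
        dup = g["timestamp"].duplicated()
        if dup.any():
            logger.warning("trip %s/%s: %d duplicate timestamps collapsed", ind, trip, int(dup.sum()))
            g = g.loc[~dup]
        if len(g) < 2:
            logger.warning("trip %s/%s: fewer than 2 usable fixes, skipped", ind, trip)
            continue
        tracks.append(Track(ind, str(trip), g.reset_index(drop=True)[["timestamp", "lon", "lat"]]))
    return tracks


def _greedy_grid_indices(t: np.ndarray, interval: float) -> np.ndarray:
    """Greedy forward selection of fixes closest to a regular time grid.

    Keeps the first fix; each subsequent kept fix is the one closest in time
    to ``last_kept + interval`` within a half-interval window.  When no fix
    falls in the window (a recording gap) the next available fix re-anchors
    the grid.
    """
    n = len(t)
    keep = [0]
    i = 0
    while True:
        target = t[keep[-1]] + interval
        lo, hi = target - interval / 2.0, target + interval / 2.0
        a = np.searchsorted(t, lo, side="left")
        b = np.searchsorted(t, hi, side="right")
        a = max(a, keep[-1] + 1)
        if a < b:
            cand = a + int(np.argmin(np.abs(t[a:b] - target)))
        else:
            # gap: first fix beyond the window, if any
            c = np.searchsorted(t, hi, side="right")
            c = max(c, keep[-1] + 1)
            if c >= n:
                break
            cand = c
        keep.append(cand)
        i = cand
        if cand == n - 1:
            break
    return np.asarray(keep, dtype=int)


def segment_speeds(fixes: pd.DataFrame, segment_id: np.ndarray | None = None) -> np.ndarray:
    """Incoming-segment ground speed (m/s) per fix; NaN at segment starts."""
    t = fixes["timestamp"].astype("int64").to_numpy() / 1e9
    d = haversine_m(
        fixes["lon"].to_numpy()[:-1], fixes["lat"].to_numpy()[:-1],
        fixes["lon"].to_numpy()[1:], fixes["lat"].to_numpy()[1:],
    )
    dt = np.diff(t)
    sp = np.full(len(fixes), np.nan)
    sp[1:] = np.asarray(d) / dt
    if segment_id is not None:
        sp[np.r_[True, np.diff(segment_id) != 0]] = np.nan
    return sp


def regularise(track: Track, interval_s: float = 60.0) -> RegularisedTrack:
    """Thin a track to a near-regular series at ``interval_s`` seconds.

    No positions are interpolated; gaps are preserved and recorded as segment
    boundaries wherever the retained inter-fix interval exceeds twice the
    nominal interval.  A track shorter than one interval is returned flagged
    unusable.
    """
    if interval_s <= 0:
        raise ValueError("interval must be positive")
    t = track.fixes["timestamp"].astype("int64").to_numpy() / 1e9
    if t[-1] - t[0] < interval_s:
        fixes = track.fixes.iloc[:1].copy().reset_index(drop=True)
        fixes["speed_ms"] = np.nan
        fixes["sitting"] = False
        fixes["segment_id"] = 0
        logger.warning("trip %s: duration below nominal interval, unusable", track.trip_id)
        return RegularisedTrack(track.individual_id, track.trip_id, fixes, interval_s, usable=False)

    keep = _greedy_grid_indices(t, interval_s)
    fixes = track.fixes.iloc[keep].reset_index(drop=True).copy()
    tk = t[keep]
    seg = np.zeros(len(keep), dtype=int)
    seg[1:] = np.cumsum(np.diff(tk) > 2.0 * interval_s)
    fixes["segment_id"] = seg
    fixes["speed_ms"] = segment_speeds(fixes, seg)
    fixes["sitting"] = False
    return RegularisedTrack(track.individual_id, track.trip_id, fixes, interval_s)


def flag_sitting(track: RegularisedTrack, speed_threshold_kmh: float = 10.0) -> RegularisedTrack:
    """Flag fixes reached below the sitting-on-water speed threshold.

    A fix is flagged when the speed of the segment arriving at it is below
    ``speed_threshold_kmh``.  Flagged fixes stay in the object but are
    excluded from downstream analysis; speeds over the retained sequence are
    recomputed once (single pass).
    """
    thr_ms = speed_threshold_kmh / 3.6
    fixes = track.fixes.copy()
    sp = fixes["speed_ms"].to_numpy()
    sitting = np.where(np.isnan(sp), False, sp < thr_ms)
    fixes["sitting"] = sitting

    out = replace(track, fixes=fixes)
    ret = fixes.loc[~sitting]
    if len(ret) >= 2:
        out.retained_speeds_ms = segment_speeds(ret, ret["segment_id"].to_numpy())
    else:
        out.retained_speeds_ms = np.full(len(ret), np.nan)
    return out


def tracks_from_frame(df: pd.DataFrame) -> list[Track]:
    """Split a long-format fix table into one Track per (individual, trip)."""
    out = []
    for (ind, trip), g in df.groupby(["individual_id", "trip_id"], sort=True):
        if len(g) < 2:
            logger.warning("trip %s/%s: fewer than 2 fixes, skipped", ind, trip)
            continue
        out.append(Track(str(ind), str(trip),
                         g[["timestamp", "lon", "lat"]].reset_index(drop=True)))
    return out


def write_tracks_csv(tracks: list[RegularisedTrack], path) -> None:
    """Write regularised tracks back to CSV with speed/sitting/segment columns."""
    frames = []
    for tr in tracks:
        f = tr.fixes.copy()
        f.insert(0, "individual_id", tr.individual_id)
        f.insert(1, "trip_id", tr.trip_id)
        f["sitting"] = f["sitting"].astype(int)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
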