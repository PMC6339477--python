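"""First-passage time (FPT) analysis and area-restricted search scale detection.

FPT at a track location is the time the animal takes to cross a circle of a
given radius centred on that location, summing the backward and forward
passage from the focal fix.  Sweeping the radius from metres to a kilometre
and finding where the variance of log-FPT across a track peaks identifies the
characteristic spatial scale of area-restricted search (ARS): at that radius
the contrast between fast directed transit and slow tortuous search is
maximal.  The working scale for behavioural classification is the median of
per-track peak radii.

Crossing instants are located by linear interpolation of distance-to-centre
along the chord between the last fix inside the circle and the first outside
— a deliberate planar approximation, accurate at the sub-kilometre radii
used here.  Recording gaps (segment boundaries from regularisation) break
passage accumulation: a passage still inside the circle when it meets a gap
or the track end is missing, not censored, which avoids a downward bias at
track edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ScaleUndetectableError
from .track_io import RegularisedTrack, haversine_m

logger = logging.getLogger(__name__)


def default_radii(r_min: float = 5.0, r_max: float = 1000.0, n: int = 40) -> np.ndarray:
    """Log-spaced radius sweep in metres (default 40 radii over 5–1,000 m)."""
    return np.geomspace(r_min, r_max, n)


@dataclass
class FptProfile:
    """Per-fix FPT across a radius sweep for one track, plus its scale score.

    ``fpt`` is a (n_fixes, n_radii) matrix in seconds with NaN where a
    passage never completes.  ``variance_profile`` is the per-radius
    dispersion statistic; ``peak_radius`` is the radius maximising it, or
    None when the profile is flat or undefined everywhere.
    """

    individual_id: str
    trip_id: str
    radii: np.ndarray
    fpt: np.ndarray
    variance_profile: np.ndarray
    peak_radius: float | None
    n_defined: np.ndarray

    def summary(self) -> dict:
        """JSON-ready per-track summary."""
        return {
            "individual_id": self.individual_id,
            "trip_id": self.trip_id,
            "peak_radius_m": self.peak_radius,
            "n_defined": {float(r): int(n) for r, n in zip(self.radii, self.n_defined)},
        }


def _directional_passage(d: np.ndarray, t: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Passage times from a focal fix in one direction, all radii at once.

    ``d``: distances from the circle centre to the fixes strictly after the
    focal one (in walking order); ``t``: their times relative to the focal
    fix (positive, increasing).  The first fix whose distance exceeds r is
    the first exit for radius r; because the running maximum of ``d`` is
    non-decreasing, that index is a single sorted lookup per radius.
    Returns NaN where the path never leaves the circle.
    """
    out = np.full(len(radii), np.nan)
    if len(d) == 0:
        return out
    cm = np.maximum.accumulate(d)
    j = np.searchsorted(cm, radii, side="right")  # first index with d > r
    ok = j < len(d)
    jj = j[ok]
    d_out = d[jj]
    d_in = np.where(jj > 0, d[np.maximum(jj - 1, 0)], 0.0)
    t_out = t[jj]
    t_in = np.where(jj > 0, t[np.maximum(jj - 1, 0)], 0.0)
    f = (radii[ok] - d_in) / (d_out - d_in)
    out[ok] = t_in + f * (t_out - t_in)
    return out


def _fpt_matrix(lon: np.ndarray, lat: np.ndarray, t: np.ndarray,
                seg: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """FPT (seconds) for every (fix, radius); NaN where undefined."""
    n = len(lon)
    radii = np.asarray(radii, dtype=float)
    out = np.full((n, len(radii)), np.nan)
    for s in np.unique(seg):
        idx = np.nonzero(seg == s)[0]
        a, b = idx[0], idx[-1] + 1
        slon, slat, st = lon[a:b], lat[a:b], t[a:b]
        m = b - a
        for k in range(m):
            d = haversine_m(slon[k], slat[k], slon, slat)
            fwd = _directional_passage(d[k + 1:], st[k + 1:] - st[k], radii)
            bwd = _directional_passage(d[:k][::-1], st[k] - st[:k][::-1], radii)
            out[a + k] = fwd + bwd
    return out


def first_passage_time(track: RegularisedTrack, fix_index: int, radius: float) -> float:
    """FPT in seconds at one retained fix for one radius; NaN if undefined.

    ``fix_index`` indexes the retained (non-sitting) fix sequence.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    ret = track.retained()
    if not 0 <= fix_index < len(ret):
        raise IndexError(f"fix_index {fix_index} out of range for {len(ret)} retained fixes")
    lon = ret["lon"].to_numpy()
    lat = ret["lat"].to_numpy()
    t = ret["timestamp"].astype("int64").to_numpy() / 1e9
    seg = ret["segment_id"].to_numpy()
    row = _fpt_matrix(lon, lat, t, seg, np.array([radius]))[fix_index]
    return float(row[0])


def fpt_profile(track: RegularisedTrack, radii: np.ndarray | None = None,
                statistic: str = "var_log", min_defined: int = 5) -> FptProfile:
    """FPT over a radius sweep plus the per-radius variance profile.

    ``statistic`` selects the dispersion score: ``"var_log"`` (variance of
    log-FPT, the default) or ``"log_var"`` (log of the variance of raw FPT) —
    a sensitivity switch; the two differ only through the log transform of
    the per-fix values.  Radii with fewer than ``min_defined`` defined FPT
    values are not scored.  Raises :class:`ScaleUndetectableError` when no
    radius can be scored.
    """
    radii = default_radii() if radii is None else np.asarray(radii, dtype=float)
    if not (np.all(radii > 0) and np.all(np.diff(radii) > 0)):
        raise ValueError("radii must be positive and strictly increasing")
    ret = track.retained()
    if len(ret) < 3:
        raise ScaleUndetectableError(f"trip {track.trip_id}: fewer than 3 retained fixes")
    lon = ret["lon"].to_numpy()
    lat = ret["lat"].to_numpy()
    t = ret["timestamp"].astype("int64").to_numpy() / 1e9
    seg = ret["segment_id"].to_numpy()

    mat = _fpt_matrix(lon, lat, t, seg, radii)
    n_def = np.sum(np.isfinite(mat), axis=0)
    var = np.full(len(radii), np.nan)
    for r in np.nonzero(n_def >= min_defined)[0]:
        vals = mat[np.isfinite(mat[:, r]), r]
        if statistic == "var_log":
            var[r] = np.var(np.log(vals), ddof=1)
        elif statistic == "log_var":
            v = np.var(vals, ddof=1)
            var[r] = np.log(v) if v > 0 else np.nan
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    if not np.any(np.isfinite(var)):
        raise ScaleUndetectableError(f"trip {track.trip_id}: no radius with >= {min_defined} defined FPTs")

    finite = var[np.isfinite(var)]
    if np.nanmax(var) < 1e-12 or np.ptp(finite) < 1e-12:
        peak = None  # flat profile: no scale structure (e.g. straight transit)
        logger.warning("trip %s: flat variance profile, no ARS scale", track.trip_id)
    else:
        peak = float(radii[np.nanargmax(var)])
    return FptProfile(track.individual_id, track.trip_id, radii, mat, var, peak, n_def)


@dataclass
class ArsScale:
    """Per-track peak radii and their median, the global working scale."""

    per_track_peaks: dict[str, float]
    global_scale: float


def ars_scale(profiles: list[FptProfile]) -> ArsScale:
    """Median of per-track peak radii; tracks without a peak are omitted."""
    peaks = {}
    for p in profiles:
        if p.peak_radius is None:
            logger.warning("trip %s: undetectable ARS scale, omitted from median", p.trip_id)
            continue
        peaks[p.trip_id] = p.peak_radius
    if not peaks:
        raise ScaleUndetectableError("no track yielded a detectable ARS scale")
    return ArsScale(peaks, float(np.median(list(peaks.values()))))


def fpt_at_scale(track: RegularisedTrack, radius: float) -> np.ndarray:
    """FPT at one working radius for every retained fix of a track."""
    ret = track.retained()
    lon = ret["lon"].to_numpy()
    lat = ret["lat"].to_numpy()
    t = ret["timestamp"].astype("int64").to_numpy() / 1e9
    seg = ret["segment_id"].to_numpy()
    return _fpt_matrix(lon, lat, t, seg, np.array([float(radius)]))[:, 0]


def profile_to_records(profile: FptProfile):
    """Long-format (fix, radius, fpt_s) records for CSV serialisation."""
    import pandas as pd

    n, r = profile.fpt.shape
    return pd.DataFrame(
        {
            "trip_id": profile.trip_id,
            "fix": np.repeat(np.arange(n), r),
            "radius_m": np.tile(profile.radii, n),
            "fpt_s": profile.fpt.ravel(),
        }
    )
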