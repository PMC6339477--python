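"""Shared fixtures and track-building helpers."""

import numpy as np
import pandas as pd
import pytest

from fptrack import Track, regularise, flag_sitting

M_PER_DEG = 6_371_000.0 * np.pi / 180.0


def make_track(lon, lat, times_s, individual="b1", trip="b1_t1") -> Track:
    """Track from raw coordinate/time arrays (seconds since a fixed origin)."""
    t0 = pd.Timestamp("2015-09-01T06:00:00Z")
    ts = t0 + pd.to_timedelta(np.asarray(times_s, dtype=float), unit="s")
    return Track(individual, trip,
                 pd.DataFrame({"timestamp": ts, "lon": lon, "lat": lat}))


def straight_track(n=60, speed_ms=10.0, interval_s=60.0, lat0=0.0, lon0=0.0) -> Track:
    """Due-east constant-speed track on the equator."""
    step_deg = speed_ms * interval_s / M_PER_DEG
    lon = lon0 + np.arange(n) * step_deg
    lat = np.full(n, lat0)
    return make_track(lon, lat, np.arange(n) * interval_s)


def crw_track(rng, n=200, interval_s=60.0, transit_speed=11.0, search_speed=4.0,
              p_switch=0.15, lon0=-32.4, lat0=-3.9, individual="crw", trip="crw_t1") -> Track:
    """Two-mode correlated random walk, independent of the package generator."""
    lon = np.empty(n)
    lat = np.empty(n)
    lon[0], lat[0] = lon0, lat0
    heading = rng.uniform(-np.pi, np.pi)
    mode = 0  # 0 transit, 1 search
    for k in range(1, n):
        if rng.random() < p_switch:
            mode = 1 - mode
        heading += rng.normal(0.0, 0.3 if mode == 0 else 2.0)
        v = transit_speed if mode == 0 else search_speed
        d = rng.gamma(9.0, v / 9.0) * interval_s
        lat[k] = lat[k - 1] + d * np.sin(heading) / M_PER_DEG
        lon[k] = lon[k - 1] + d * np.cos(heading) / (M_PER_DEG * np.cos(np.radians(lat[k - 1])))
    return make_track(lon, lat, np.arange(n) * interval_s, individual, trip)


def regularised(track: Track, interval_s: float = 60.0, threshold_kmh: float = 10.0):
    return flag_sitting(regularise(track, interval_s), threshold_kmh)


@pytest.fixture(scope="session")
def small_sim():
    """A small but structurally complete synthetic study (session-cached)."""
    from fptrack import SimConfig, simulate_tracks

    cfg = SimConfig(n_individuals=4, trips_min=1, trips_max=2,
                    trip_duration_h=4.0, seed=11)
    return simulate_tracks(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
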