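"""Geometry, segmentation and daily GPS-feature tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mobrec import gps_features as g
from tests.conftest import make_gps_frame

HOME = (45.4384, 10.9916)


# ---------------------------------------------------------------------------
# haversine
# ---------------------------------------------------------------------------

def test_haversine_identity():
    assert g.haversine_m(45.0, 11.0, 45.0, 11.0) == 0.0


def test_haversine_one_arcminute_lat():
    # 0.01 deg of latitude on the WGS84 mean radius, against the spherical
    # law of cosines evaluated independently
    d = g.haversine_m(45.4384, 10.9916, 45.4484, 10.9916)
    assert d == pytest.approx(1111.95, abs=0.5)


def test_haversine_matches_law_of_cosines():
    rng = np.random.default_rng(0)
    for _ in range(50):
        la1, la2 = rng.uniform(-60, 60, 2)
        lo1, lo2 = rng.uniform(-170, 170, 2)
        p1, p2 = np.radians([la1, la2])
        dl = np.radians(lo2 - lo1)
        cos_c = np.clip(np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl), -1, 1)
        loc = g.EARTH_RADIUS_M * np.arccos(cos_c)
        assert g.haversine_m(la1, lo1, la2, lo2) == pytest.approx(loc, abs=1.0, rel=1e-6)


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.tuples(st.floats(-60, 60), st.floats(-170, 170)),
                min_size=3, max_size=3))
def test_haversine_triangle_inequality(tri):
    (a, b, c) = tri
    ab = g.haversine_m(a[0], a[1], b[0], b[1])
    bc = g.haversine_m(b[0], b[1], c[0], c[1])
    ac = g.haversine_m(a[0], a[1], c[0], c[1])
    assert ac <= ab + bc + 1e-6


def test_haversine_rejects_nonfinite():
    with pytest.raises(ValueError):
        g.haversine_m(np.nan, 0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p,expected", [
    ([1.0], 0.0),
    ([0.5, 0.5], np.log(2)),
    ([0.6], -0.6 * np.log(0.6)),
    ([], 0.0),
    ([0.0, 0.0], 0.0),
])
def test_entropy_known_values(p, expected):
    assert g.entropy_nats(p) == pytest.approx(expected, abs=1e-12)


def test_entropy_rejects_invalid():
    with pytest.raises(ValueError):
        g.entropy_nats([1.2])
    with pytest.raises(ValueError):
        g.entropy_nats([-0.1])


@settings(max_examples=100, derandomize=True)
@given(st.integers(2, 6), st.floats(0.2, 1.0))
def test_entropy_maximized_at_uniform(k, total):
    """For fixed support size and total mass, the uniform vector maximizes
    -sum p ln p (checked against perturbed vectors on a simplex grid)."""
    uniform = np.full(k, total / k)
    h_u = g.entropy_nats(uniform)
    rng = np.random.default_rng(k)
    for _ in range(10):
        w = rng.dirichlet(np.ones(k)) * total
        assert g.entropy_nats(w) <= h_u + 1e-9


# ---------------------------------------------------------------------------
# pause segmentation
# ---------------------------------------------------------------------------

def _trace(points_per_leg):
    """Concatenate (duration_s, lat, lon) stationary legs into a 1 Hz trace."""
    t, lat, lon = [], [], []
    now = 0.0
    for dur, la, lo in points_per_leg:
        n = int(dur)
        t.extend(now + np.arange(n))
        lat.extend([la] * n)
        lon.extend([lo] * n)
        now += dur
    return make_gps_frame(t, lat, lon)


def test_stationary_day_single_pause():
    tr = _trace([(7200, *HOME)])
    pauses = g.segment_pauses(tr)
    assert len(pauses) == 1
    assert pauses.iloc[0]["duration_s"] == pytest.approx(7199, abs=2)


def test_two_clusters_with_transit_two_pauses():
    b = (HOME[0] + 0.0045, HOME[1])  # ~500 m north
    # 20 min at home, 6-min transit sampled coarsely, 20 min at B
    t = list(np.arange(0, 1200))
    lat = [HOME[0]] * 1200
    lon = [HOME[1]] * 1200
    for i, f in enumerate(np.linspace(0, 1, 40)):
        t.append(1200 + i * 9)
        lat.append(HOME[0] + f * 0.0045)
        lon.append(HOME[1])
    t += list(1560 + np.arange(0, 1200))
    lat += [b[0]] * 1200
    lon += [b[1]] * 1200
    pauses = g.segment_pauses(make_gps_frame(t, lat, lon))
    assert len(pauses) == 2


def test_continuous_motion_no_pause():
    # 1.4 m/s straight line for 30 min at 1 Hz: displacement exceeds the
    # pause radius well before the 300 s minimum
    n = 1800
    t = np.arange(n)
    lat = HOME[0] + 1.4 * t * g.EARTH_RADIUS_M ** -1 * (180 / np.pi)
    pauses = g.segment_pauses(make_gps_frame(t, lat, np.full(n, HOME[1])))
    assert len(pauses) == 0


def test_empty_trace_empty_pauses():
    assert len(g.segment_pauses(make_gps_frame([], [], []))) == 0


def test_max_gap_splits_pause():
    tr1 = _trace([(1200, *HOME)])
    tr2 = _trace([(1200, *HOME)])
    tr2["t"] += 1200 + 7200  # 2 h silent gap
    pauses = g.segment_pauses(pd.concat([tr1, tr2], ignore_index=True))
    assert len(pauses) == 2  # the gap is not bridged


# ---------------------------------------------------------------------------
# flights
# ---------------------------------------------------------------------------

def _moving_trace(start, heading_deg_series, speed=8.0, dt=1.0):
    lat, lon = [start[0]], [start[1]]
    k = 180.0 / (np.pi * g.EARTH_RADIUS_M)
    for h in heading_deg_series:
        lat.append(lat[-1] + speed * dt * np.sin(np.radians(h)) * k)
        lon.append(lon[-1] + speed * dt * np.cos(np.radians(h)) * k
                   / np.cos(np.radians(lat[-1])))
    t = np.arange(len(lat), dtype=float)
    return make_gps_frame(t, lat, lon)


def test_straight_transit_single_flight():
    tr = _moving_trace(HOME, [90.0] * 125)  # 1 km due north
    fl = g.extract_flights(tr, pd.DataFrame(columns=g.PAUSE_COLUMNS))
    assert len(fl) == 1
    assert fl.iloc[0]["length_m"] == pytest.approx(1000, rel=0.02)


def test_right_angle_two_flights():
    tr = _moving_trace(HOME, [90.0] * 63 + [0.0] * 63)  # north 500 m, east 500 m
    fl = g.extract_flights(tr, pd.DataFrame(columns=g.PAUSE_COLUMNS))
    assert len(fl) == 2
    assert np.allclose(fl["length_m"], 500, rtol=0.05)


def test_stationary_day_no_flights():
    tr = _trace([(3600, *HOME)])
    pauses = g.segment_pauses(tr)
    fl = g.extract_flights(tr, pauses)
    assert len(fl) == 0


def test_daily_distance_sums_flights():
    fl = pd.DataFrame({"length_m": [400.0, 600.0]})
    assert g.daily_distance_km(fl) == pytest.approx(1.0)
    assert g.daily_distance_km(pd.DataFrame(columns=g.FLIGHT_COLUMNS)) == 0.0


def test_distance_invariant_under_translation_and_timeshift():
    tr = _moving_trace(HOME, [90.0] * 60 + [0.0] * 60)
    fl0 = g.extract_flights(tr, pd.DataFrame(columns=g.PAUSE_COLUMNS))
    shifted = tr.copy()
    shifted["lat"] += 0.05
    shifted["lon"] += 0.08
    shifted["t"] += 3600.0
    fl1 = g.extract_flights(shifted, pd.DataFrame(columns=g.PAUSE_COLUMNS))
    assert g.daily_distance_km(fl1) == pytest.approx(
        g.daily_distance_km(fl0), rel=1e-3)


# ---------------------------------------------------------------------------
# significant locations / home
# ---------------------------------------------------------------------------

def _pauses(entries):
    """entries: (lat, lon, duration_s, start_s)"""
    rows = [(s, s + d, la, lo, d, int(d)) for la, lo, d, s in entries]
    return pd.DataFrame(rows, columns=g.PAUSE_COLUMNS)


def test_single_cluster_single_location():
    ps = _pauses([(HOME[0] + i * 1e-5, HOME[1], 1200, i * 5000) for i in range(5)])
    locs = g.find_significant_locations(ps, seed=0)
    assert len(locs) == 1


def test_two_groups_60m_apart_two_locations():
    b = (HOME[0] + 60 / 111320.0, HOME[1])
    ps = _pauses([(HOME[0], HOME[1], 1200, 0), (HOME[0], HOME[1], 1500, 5000),
                  (HOME[0], HOME[1], 1000, 10000),
                  (b[0], b[1], 1100, 15000), (b[0], b[1], 1300, 20000),
                  (b[0], b[1], 1200, 25000)])
    locs = g.find_significant_locations(ps, seed=0)
    assert len(locs) == 2


def test_short_pauses_no_locations():
    ps = _pauses([(HOME[0], HOME[1], 600, 0), (HOME[0], HOME[1], 600, 3000)])
    assert len(g.find_significant_locations(ps, seed=0)) == 0


def test_detect_home_night_dominance():
    """A holds all night pauses over 3 days, B all daytime pauses -> A."""
    day = 86400
    b = (HOME[0] + 0.01, HOME[1])
    entries = []
    for d in range(3):
        entries.append((HOME[0], HOME[1], 8 * 3600, d * day))          # 00-08 at A
        entries.append((b[0], b[1], 8 * 3600, d * day + 9 * 3600))     # 09-17 at B
        entries.append((HOME[0], HOME[1], 3.5 * 3600, d * day + 20 * 3600))  # 20-23:30 A
    ps = _pauses(entries)
    locs = g.find_significant_locations(ps, seed=0)
    locs = g.detect_home(locs, ps, tz="UTC")
    home = locs[locs["is_home"]].iloc[0]
    assert g.haversine_m(home["lat"], home["lon"], *HOME) < 10


def test_detect_home_tiebreak_daytime():
    day = 86400
    b = (HOME[0] + 0.01, HOME[1])
    entries = []
    # equal night time at A and B; A has extra daytime
    entries.append((HOME[0], HOME[1], 4 * 3600, 0))            # 00-04 A
    entries.append((b[0], b[1], 4 * 3600, 4 * 3600))           # 04-08 B
    entries.append((HOME[0], HOME[1], 5 * 3600, 10 * 3600))    # 10-15 A (daytime)
    ps = _pauses(entries)
    locs = g.find_significant_locations(ps, seed=0)
    locs = g.detect_home(locs, ps, tz="UTC")
    home = locs[locs["is_home"]].iloc[0]
    assert g.haversine_m(home["lat"], home["lon"], *HOME) < 10


def test_detect_home_requires_locations():
    with pytest.raises(ValueError):
        g.detect_home(pd.DataFrame(columns=g.SIGLOC_COLUMNS),
                      pd.DataFrame(columns=g.PAUSE_COLUMNS))


def test_single_location_is_home():
    ps = _pauses([(HOME[0], HOME[1], 1200, 0)])
    locs = g.detect_home(g.find_significant_locations(ps, seed=0), ps, tz="UTC")
    assert locs["is_home"].sum() == 1


# ---------------------------------------------------------------------------
# day profile / home duration / summary
# ---------------------------------------------------------------------------

def test_day_profile_seconds_tally():
    """12 h at home, 6 h at B, rest unobserved -> p = (0.5, 0.25)."""
    b = (HOME[0] + 0.01, HOME[1])
    ps = _pauses([(HOME[0], HOME[1], 12 * 3600, 0), (b[0], b[1], 6 * 3600, 13 * 3600)])
    locs = g.find_significant_locations(ps, seed=0)
    prof = g.day_location_profile(ps, locs)
    assert sorted(np.round(prof.p[prof.p > 0], 4)) == [0.25, 0.5]
    assert prof.count == 2
    assert prof.p.sum() + prof.transit_fraction <= 1.0


def test_day_profile_no_pauses():
    locs = g.find_significant_locations(
        _pauses([(HOME[0], HOME[1], 1200, 0)]), seed=0)
    prof = g.day_location_profile(pd.DataFrame(columns=g.PAUSE_COLUMNS), locs)
    assert prof.count == 0


def test_home_duration_cap_and_missing():
    ps = _pauses([(HOME[0], HOME[1], 30 * 3600, 0)])  # malformed long pause
    assert g.daily_home_duration_h(ps, *HOME) == 24.0
    assert g.daily_home_duration_h(pd.DataFrame(columns=g.PAUSE_COLUMNS), *HOME) == 0.0


def test_summarize_day_stationary_home():
    ps = _pauses([(HOME[0], HOME[1], 86350, 0)])
    locs = g.detect_home(g.find_significant_locations(ps, seed=0), ps, tz="UTC")
    s = g.summarize_day(pd.DataFrame(columns=g.FLIGHT_COLUMNS), ps, locs,
                        *HOME)
    assert s["distance_km"] == 0.0
    assert s["home_hours"] == pytest.approx(24.0, abs=0.2)
    assert s["sig_loc_count"] == 1
    assert s["sig_loc_entropy"] == 0.0


def test_summarize_day_missing():
    s = g.summarize_day(pd.DataFrame(columns=g.FLIGHT_COLUMNS),
                        pd.DataFrame(columns=g.PAUSE_COLUMNS),
                        pd.DataFrame(columns=g.SIGLOC_COLUMNS),
                        np.nan, np.nan, has_gps=False)
    assert all(np.isnan(v) for v in s.values())
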