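"""Location-derived daily mobility features.

Implements the four GPS variables of the daily-summary table:

* **Distance Traveled** (km) — the sum of flight lengths, a flight being the
  longest straight-line displacement between pauses or directional changes.
* **Significant Location Count** — number of significant locations (clusters
  of >= 15-min pauses whose centers are >= 50 m apart, found per patient over
  the whole follow-up) visited at any point of the day.
* **Significant Location Entropy** (nats) — -sum p_i ln p_i over the day's
  non-zero significant-location occupancy shares.
* **Home Duration** (hours) — pause time at the home location, home being the
  significant location with the most visit time between 20:00 and 08:00 over
  the follow-up.

All geometry is haversine on the WGS84 mean radius; coordinates are never
projected except locally (equirectangular, meters) for clustering and
segmentation decisions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import _kernels

EARTH_RADIUS_M = 6_371_008.8

PAUSE_COLUMNS = ["start", "end", "lat", "lon", "duration_s", "n_points"]
FLIGHT_COLUMNS = ["start", "end", "lat0", "lon0", "lat1", "lon1", "length_m"]
SIGLOC_COLUMNS = ["loc_id", "lat", "lon", "total_pause_s", "is_home"]


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in meters (vectorized).

    Symmetric, non-negative, zero iff the coordinates coincide.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(a, dtype=float) for a in (lat1, lon1, lat2, lon2))
    if not (np.all(np.isfinite(lat1)) and np.all(np.isfinite(lon1))
            and np.all(np.isfinite(lat2)) and np.all(np.isfinite(lon2))):
        raise ValueError("haversine_m requires finite coordinates")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _planar(lat, lon, lat0=None, lon0=None):
    """Equirectangular projection to meters around (lat0, lon0)."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat0 is None:
        lat0 = float(np.mean(lat)) if lat.size else 0.0
    if lon0 is None:
        lon0 = float(np.mean(lon)) if lon.size else 0.0
    k = np.pi / 180.0 * EARTH_RADIUS_M
    x = (lon - lon0) * np.cos(np.radians(lat0)) * k
    y = (lat - lat0) * k
    return x, y, lat0, lon0


def segment_pauses(points: pd.DataFrame, pause_radius_m: float = 50.0,
                   min_pause_s: float = 300.0, max_gap_s: float = 1800.0) -> pd.DataFrame:
    """Detect pauses in a time-sorted GPS trace.

    A pause is a maximal contiguous run of points staying within
    ``pause_radius_m`` of the run's running centroid, kept when its span is at
    least ``min_pause_s``.  Runs are also broken at observation gaps longer
    than ``max_gap_s`` (device silence is not evidence of staying put).
    """
    if len(points) == 0:
        return pd.DataFrame(columns=PAUSE_COLUMNS)
    t = points["t"].to_numpy(dtype=float)
    lat = points["lat"].to_numpy(dtype=float)
    lon = points["lon"].to_numpy(dtype=float)
    x, y, _, _ = _planar(lat, lon)
    starts, ends = _kernels.pause_runs(t, x, y, float(pause_radius_m), float(max_gap_s))
    rows = []
    for s, e in zip(starts, ends):
        dur = t[e] - t[s]
        if dur >= min_pause_s:
            rows.append((t[s], t[e], lat[s:e + 1].mean(), lon[s:e + 1].mean(),
                         dur, int(e - s + 1)))
    return pd.DataFrame(rows, columns=PAUSE_COLUMNS)


def _pause_index_ranges(points: pd.DataFrame, pauses: pd.DataFrame):
    t = points["t"].to_numpy(dtype=float)
    s_idx = np.searchsorted(t, pauses["start"].to_numpy(dtype=float), side="left")
    e_idx = np.searchsorted(t, pauses["end"].to_numpy(dtype=float), side="right") - 1
    return s_idx, e_idx


def extract_flights(points: pd.DataFrame, pauses: pd.DataFrame,
                    heading_change_deg: float = 30.0, min_vertex_m: float = 15.0,
                    max_gap_s: float = 1800.0) -> pd.DataFrame:
    """Split inter-pause (and trace-edge) segments into flights.

    Segments are decimated to vertices >= ``min_vertex_m`` apart and split
    where the heading between consecutive vertex displacements turns by more
    than ``heading_change_deg``.  Each flight runs from the first to the last
    point of its sub-segment; its length is the haversine chord between them.
    """
    if len(points) < 2:
        return pd.DataFrame(columns=FLIGHT_COLUMNS)
    t = points["t"].to_numpy(dtype=float)
    lat = points["lat"].to_numpy(dtype=float)
    lon = points["lon"].to_numpy(dtype=float)
    x, y, _, _ = _planar(lat, lon)

    if len(pauses):
        ps, pe = _pause_index_ranges(points, pauses)
        bounds = []
        prev_end = 0
        for s, e in zip(ps, pe):
            bounds.append((prev_end, s))
            prev_end = e
        bounds.append((prev_end, len(t) - 1))
    else:
        bounds = [(0, len(t) - 1)]

    rows = []
    rad = np.radians(heading_change_deg)
    for a, b in bounds:
        if b - a < 1:
            continue
        f0, f1 = _kernels.flight_splits(t, x, y, int(a), int(b),
                                        float(min_vertex_m), float(rad),
                                        float(max_gap_s))
        for i, j in zip(f0, f1):
            length = float(haversine_m(lat[i], lon[i], lat[j], lon[j]))
            rows.append((t[i], t[j], lat[i], lon[i], lat[j], lon[j], length))
    return pd.DataFrame(rows, columns=FLIGHT_COLUMNS)


def daily_distance_km(flights: pd.DataFrame) -> float:
    """Sum of flight lengths, in km."""
    if len(flights) == 0:
        return 0.0
    return float(flights["length_m"].sum()) / 1000.0


def find_significant_locations(pauses: pd.DataFrame, min_pause_s: float = 900.0,
                               separation_m: float = 50.0, seed: int = 0,
                               max_k: int = 30) -> pd.DataFrame:
    """Cluster a patient's qualifying pauses into significant locations.

    Only pauses of duration >= ``min_pause_s`` participate.  Duration-weighted
    k-means is run for k = 1, 2, ... and the smallest k whose maximum
    within-cluster point-to-center distance falls below ``separation_m / 2``
    is selected; the cluster centers are the significant locations.  The
    half-separation radius makes pause groups separated by just over
    ``separation_m`` split into distinct locations, while centers closer
    than ``separation_m`` are merged (duration-weighted), so surviving
    locations are pairwise at least ``separation_m`` apart.
    """
    qual = pauses[pauses["duration_s"] >= min_pause_s]
    if len(qual) == 0:
        return pd.DataFrame(columns=SIGLOC_COLUMNS)
    lat = qual["lat"].to_numpy(dtype=float)
    lon = qual["lon"].to_numpy(dtype=float)
    w = qual["duration_s"].to_numpy(dtype=float)
    x, y, lat0, lon0 = _planar(lat, lon)
    X = np.column_stack([x, y])
    n = len(qual)
    k_cap = min(max_k, n)
    centers = None
    labels = None
    for k in range(1, k_cap + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(X, sample_weight=w)
        d = np.linalg.norm(X - km.cluster_centers_[labels], axis=1)
        centers = km.cluster_centers_
        if d.max() < separation_m / 2.0:
            break

    # honor the pairwise-separation invariant: merge centers closer than
    # separation_m (duration-weighted)
    totals = np.array([w[labels == i].sum() for i in range(len(centers))])
    merged = True
    while merged and len(centers) > 1:
        merged = False
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                if np.linalg.norm(centers[i] - centers[j]) < separation_m:
                    wi, wj = totals[i], totals[j]
                    centers[i] = (centers[i] * wi + centers[j] * wj) / (wi + wj)
                    totals[i] = wi + wj
                    centers = np.delete(centers, j, axis=0)
                    totals = np.delete(totals, j)
                    labels = np.where(labels == j, i, labels)
                    labels = np.where(labels > j, labels - 1, labels)
                    merged = True
                    break
            if merged:
                break

    k = np.pi / 180.0 * EARTH_RADIUS_M
    out_lat = lat0 + centers[:, 1] / k
    out_lon = lon0 + centers[:, 0] / (k * np.cos(np.radians(lat0)))
    order = np.argsort(-totals)  # most-visited first, stable ids
    return pd.DataFrame({
        "loc_id": np.arange(len(order)),
        "lat": out_lat[order],
        "lon": out_lon[order],
        "total_pause_s": totals[order],
        "is_home": False,
    })


def attribute_pauses(pauses: pd.DataFrame, sig_locs: pd.DataFrame,
                     separation_m: float = 50.0) -> np.ndarray:
    """Map each pause to the nearest significant location within
    ``separation_m`` (else -1)."""
    if len(pauses) == 0 or len(sig_locs) == 0:
        return np.full(len(pauses), -1, dtype=int)
    d = haversine_m(pauses["lat"].to_numpy()[:, None], pauses["lon"].to_numpy()[:, None],
                    sig_locs["lat"].to_numpy()[None, :], sig_locs["lon"].to_numpy()[None, :])
    nearest = np.argmin(d, axis=1)
    ok = d[np.arange(len(pauses)), nearest] <= separation_m
    return np.where(ok, sig_locs["loc_id"].to_numpy()[nearest], -1)


def night_overlap_s(start: float, end: float, tz: str,
                    night_start_h: int = 20, night_end_h: int = 8) -> float:
    """Seconds of [start, end] (epoch s) falling inside the nightly
    [night_start_h, night_end_h) local windows."""
    s = pd.Timestamp(start, unit="s", tz="UTC").tz_convert(tz)
    e = pd.Timestamp(end, unit="s", tz="UTC").tz_convert(tz)
    total = (e - s).total_seconds()
    # daytime window is [night_end_h, night_start_h) each local day
    day0 = s.normalize()
    n_days = int((e.normalize() - day0).days) + 1
    day_sec = 0.0
    for i in range(n_days):
        d = day0 + pd.Timedelta(days=i)
        w0 = d + pd.Timedelta(hours=night_end_h)
        w1 = d + pd.Timedelta(hours=night_start_h)
        lo = max(s, w0)
        hi = min(e, w1)
        if hi > lo:
            day_sec += (hi - lo).total_seconds()
    return max(total - day_sec, 0.0)


def detect_home(sig_locs: pd.DataFrame, pauses: pd.DataFrame, tz: str = "UTC",
                separation_m: float = 50.0) -> pd.DataFrame:
    """Flag the home significant location.

    Home is the significant location with the greatest pause time inside the
    nightly [20:00, 08:00) local windows over the whole follow-up; ties break
    by larger all-day pause time, then smaller id.
    """
    if len(sig_locs) == 0:
        raise ValueError("no significant locations; home is not assignable")
    loc_of = attribute_pauses(pauses, sig_locs, separation_m)
    night = np.zeros(len(sig_locs))
    allday = np.zeros(len(sig_locs))
    ids = sig_locs["loc_id"].to_numpy()
    for i, (_, p) in enumerate(pauses.iterrows()):
        li = loc_of[i]
        if li < 0:
            continue
        j = int(np.where(ids == li)[0][0])
        night[j] += night_overlap_s(p["start"], p["end"], tz)
        allday[j] += p["duration_s"]
    order = np.lexsort((ids, -allday, -night))
    out = sig_locs.copy()
    out["is_home"] = False
    out.iloc[order[0], out.columns.get_loc("is_home")] = True
    return out


def daily_home_duration_h(day_pauses: pd.DataFrame, home_lat: float, home_lon: float,
                          separation_m: float = 50.0) -> float:
    """Hours of the day's pause time whose centroid lies within
    ``separation_m`` of home, capped at 24.  NaN when the day has no pauses
    is handled by the caller (missing-day convention)."""
    if len(day_pauses) == 0:
        return 0.0
    d = haversine_m(day_pauses["lat"].to_numpy(), day_pauses["lon"].to_numpy(),
                    home_lat, home_lon)
    sec = day_pauses["duration_s"].to_numpy()[d <= separation_m].sum()
    return min(float(sec) / 3600.0, 24.0)


@dataclass
class DayLocationProfile:
    """Per-day occupancy fractions of significant locations.

    ``p`` are day fractions (denominator 86,400 s), so ``sum(p) +
    transit_fraction <= 1`` with unobserved time making the inequality
    strict.  ``loc_ids`` aligns with ``p``.
    """
    p: np.ndarray
    loc_ids: np.ndarray
    transit_fraction: float = 0.0

    @property
    def count(self) -> int:
        return int(np.sum(self.p > 0))


def day_location_profile(day_pauses: pd.DataFrame, sig_locs: pd.DataFrame,
                         separation_m: float = 50.0,
                         transit_s: float = 0.0) -> DayLocationProfile:
    """Occupancy day-fractions p_i = (pause seconds at location i) / 86400."""
    if len(sig_locs) == 0:
        return DayLocationProfile(np.zeros(0), np.zeros(0, dtype=int),
                                  transit_s / 86400.0)
    ids = sig_locs["loc_id"].to_numpy()
    sec = np.zeros(len(ids))
    loc_of = attribute_pauses(day_pauses, sig_locs, separation_m)
    for li, dur in zip(loc_of, day_pauses["duration_s"].to_numpy() if len(day_pauses) else []):
        if li >= 0:
            sec[np.where(ids == li)[0][0]] += dur
    return DayLocationProfile(sec / 86400.0, ids, transit_s / 86400.0)


def entropy_nats(p) -> float:
    """Shannon entropy -sum_{p_i>0} p_i ln p_i (natural log).

    The vector is used as given (no normalization); an empty or all-zero
    vector has entropy 0.  Components must lie in [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return 0.0
    if np.any(~np.isfinite(p)) or np.any(p < 0):
        raise ValueError("occupancy fractions must be finite and >= 0")
    if np.any(p > 1.0 + 1e-12):
        raise ValueError("occupancy fractions cannot exceed 1")
    nz = p[p > 0]
    if nz.size == 0:
        return 0.0
    return float(-(nz * np.log(nz)).sum() + 0.0)


def summarize_day(flights: pd.DataFrame, day_pauses: pd.DataFrame,
                  sig_locs: pd.DataFrame, home_lat: float, home_lon: float,
                  separation_m: float = 50.0, has_gps: bool = True) -> dict:
    """One day's four GPS variables.

    A day with no GPS observations yields all-missing fields.  Daily entropy
    is computed on the day's occupancy shares renormalized over significant-
    location time (a day spent at a single place has entropy 0 regardless of
    how much of it was observed).
    """
    if not has_gps:
        return {"distance_km": np.nan, "home_hours": np.nan,
                "sig_loc_count": np.nan, "sig_loc_entropy": np.nan}
    profile = day_location_profile(day_pauses, sig_locs, separation_m)
    tot = profile.p.sum()
    shares = profile.p / tot if tot > 0 else profile.p
    return {
        "distance_km": daily_distance_km(flights),
        "home_hours": daily_home_duration_h(day_pauses, home_lat, home_lon, separation_m),
        "sig_loc_count": float(profile.count),
        "sig_loc_entropy": entropy_nats(shares),
    }
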