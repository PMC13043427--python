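"""Synthetic post-surgical cohort generator.

Generates raw duty-cycled GPS traces (1 min on / 4 min off), accelerometer
bursts (10 s on / 10 s off), PROM responses and patient metadata from
ground-truth daily schedules, for a two-arm (anterior/posterior approach)
cohort recovering over a 70-day follow-up.

Each simulated day is an explicit schedule: nights at home, a daytime
excursion visiting 0..4 significant places, "ambient drift" (a chain of
sub-15-minute dwells hopping >= 60 m, representing errands and pottering that
never creates a significant location), brisk-walk bouts that carry the step
signal, and straight vehicle-speed transits whose corners coincide with
stops.  The schedule realizes per-day latent targets drawn from per-arm
log-linear (or linear, for home hours) trajectories, so the cohort's pooled
week-1 and week-5 means match the calibration targets by construction.

Ground truth per patient-day records the exact haversine path length, stay
occupancies (shares of significant-location time), entropy of those shares,
and steps = cadence x walking seconds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .gps_features import haversine_m, entropy_nats, EARTH_RADIUS_M
from .io_config import PatientMeta, CohortBundle

DEG_M = 180.0 / (np.pi * EARTH_RADIUS_M)  # degrees latitude per meter

WEEK1_DAYS = np.arange(1, 8)
WEEK5_DAYS = np.arange(29, 36)


class ScheduleError(ValueError):
    """A day plan's stays overlap or are otherwise inconsistent."""


class ConfigError(ValueError):
    """Infeasible cohort configuration."""


# ---------------------------------------------------------------------------
# calibration helpers
# ---------------------------------------------------------------------------

def _week_factor(b: float, days: np.ndarray) -> float:
    return float(np.mean(np.exp(b * days)))


def solve_log_trajectory(t1: float, t5: float,
                         days1=WEEK1_DAYS, days5=WEEK5_DAYS) -> tuple[float, float]:
    """Intercept/slope (a, b) of exp(a + b*day) whose week-1 and week-5 day
    means equal t1 and t5.  Closed form: the two week windows are 28 days
    apart, so the ratio pins the slope exactly."""
    if t1 <= 0 or t5 <= 0:
        raise ConfigError("log-link targets must be positive")
    b = math.log(t5 / t1) / 28.0
    a = math.log(t1) - math.log(_week_factor(b, days1))
    return a, b


def solve_linear_trajectory(t1: float, t5: float) -> tuple[float, float]:
    """(a, b) of a + b*day matching week-1/week-5 means (day means 4 and 32)."""
    b = (t5 - t1) / 28.0
    a = t1 - 4.0 * b
    return a, b


def split_arms_ratio(t1: float, t5: float, r1: float, r5: float,
                     n_a: int, n_p: int) -> dict:
    """Per-arm week targets when the anterior/posterior mean ratio is (r1, r5)
    and the pooled means must equal (t1, t5)."""
    n = n_a + n_p
    p1 = n * t1 / (n_a * r1 + n_p)
    p5 = n * t5 / (n_a * r5 + n_p)
    return {"anterior": (r1 * p1, r5 * p5), "posterior": (p1, p5)}


def split_arms_delta(t1: float, t5: float, d1: float, d5: float,
                     n_a: int, n_p: int) -> dict:
    """Per-arm week targets when the anterior-minus-posterior difference is
    (d1, d5) and the pooled means must equal (t1, t5)."""
    n = n_a + n_p
    a1 = t1 + n_p * d1 / n
    a5 = t5 + n_p * d5 / n
    return {"anterior": (a1, a5), "posterior": (a1 - d1, a5 - d5)}


def binomial_pmf(p: float, n: int) -> np.ndarray:
    k = np.arange(n + 1)
    c = np.array([math.comb(n, int(i)) for i in k], dtype=float)
    return c * p ** k * (1.0 - p) ** (n - k)


def solve_truncated_poisson_rate(target_mean: float, kmax: int) -> float:
    """lam such that E[min(Poisson(lam), kmax)] = target_mean (bisection)."""
    if target_mean <= 0:
        return 0.0
    if target_mean >= kmax:
        raise ConfigError(f"cannot reach mean {target_mean} with cap {kmax}")
    lo, hi = 1e-9, 10.0 * (target_mean + 1)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        m = float(np.sum(np.arange(kmax + 1) * truncated_poisson_pmf(mid, kmax)))
        if m < target_mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _entropy_mc_draws(lam: float, n_places: int, h_mean: float, h_sd: float,
                      h_lo: float, h_hi: float, count_sigma: float,
                      visit_sigma: float, n_draws: int = 400,
                      seed: int = 777) -> dict:
    """Frozen noise draws for the visit-duration solver, mirroring the
    generator's day-level draw pipeline."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, int(lam * 1e6),
                                                        int(h_mean * 1e3)]))
    m = np.exp(rng.normal(0.0, count_sigma, n_draws) - count_sigma ** 2 / 2.0)
    x = np.minimum(lam * m, float(n_places))
    N = x.astype(int) + (rng.random(n_draws) < (x - x.astype(int))).astype(int)
    H = np.clip(rng.normal(h_mean, h_sd, n_draws), h_lo, h_hi)
    V = np.exp(rng.normal(0.0, visit_sigma, (n_draws, n_places)))
    return {"N": N, "H": H, "V": V}


def _mc_mean_entropy(visit_h: float, draws: dict, min_visit_h: float = 0.35) -> float:
    """Mean share entropy over frozen draws for a candidate visit duration."""
    N, H, V = draws["N"], draws["H"], draws["V"]
    out = np.zeros(len(N))
    for n in range(1, V.shape[1] + 1):
        sel = N == n
        if not sel.any():
            continue
        v = np.maximum(visit_h * V[sel, :n], min_visit_h)
        tot = H[sel] + v.sum(axis=1)
        sh = H[sel] / tot
        e = -sh * np.log(sh)
        sv = v / tot[:, None]
        e = e - (sv * np.log(sv)).sum(axis=1)
        out[sel] = e
    return float(out.mean())


def solve_visit_hours_mc(target_entropy: float, draws: dict,
                         v_min: float = 0.35, v_max: float = 3.5) -> float:
    """Visit duration whose Monte-Carlo expected realized entropy (over the
    generator's own noise structure) matches the target."""
    lo_val = _mc_mean_entropy(v_min, draws)
    hi_val = _mc_mean_entropy(v_max, draws)
    if target_entropy <= lo_val:
        return v_min
    if target_entropy >= hi_val:
        return v_max
    lo, hi = v_min, v_max
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if _mc_mean_entropy(mid, draws) < target_entropy:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

# Table-4-scale pooled calibration targets: (week-1 mean, week-5 mean)
POOLED_TARGETS = {
    "distance_km": (3.04, 13.89),
    "home_hours": (14.63, 14.05),
    "sig_loc_count": (1.33, 2.44),
    "sig_loc_entropy": (0.10, 0.26),
    "steps": (108.83, 250.0),
}

# anterior-vs-posterior contrasts: ratios for log-link variables, absolute
# differences (hours) for home duration.  Anterior patients start higher and
# recover steeper for steps and count; their home time falls while posterior
# home time rises; distance trajectories are arm-neutral.
ARM_RATIOS = {
    "distance_km": (1.0, 1.0),
    "sig_loc_count": (1.25, 1.35),
    "sig_loc_entropy": (1.3, 1.3),
    "steps": (1.9, 1.2),
}
HOME_DELTAS = (-0.8, -1.5)

PROM_LINK_DEFAULTS = {
    # instrument: (anchor variable, target Pearson r, location, scale)
    "VAS": ("distance_km", -0.358, 4.0, 2.2),
    "mJOA": ("steps", 0.403, 13.5, 1.5),
    "ODI": ("distance_km", -0.409, 27.0, 12.0),
    "NDI": ("distance_km", -0.279, 24.0, 11.0),
}
PROM_RANGES = {"VAS": (0, 10), "mJOA": (0, 18), "ODI": (0, 100), "NDI": (0, 100)}
WEEKLY_RESPONSE = {"mJOA": 0.71, "ODI": 0.74, "NDI": 0.69}


@dataclass
class CohortConfig:
    """Generator parameters.

    ``trajectories`` maps variable -> arm -> (intercept, slope) on the
    variable's link scale (log for distance/steps/count/entropy, identity
    for home hours).  The default instance is calibrated so the pooled
    week-1/week-5 ground-truth means reproduce the study-scale targets.
    """
    n_anterior: int = 6
    n_posterior: int = 7
    follow_up_days: int = 70
    plateau_day: int = 45  # recovery levels off; log-linear growth stops here
    trajectories: dict = field(default_factory=dict)
    # geography
    n_places: int = 4
    place_radii_km: tuple = (0.5, 1.2, 2.5, 4.0)
    # duty cycles / sensors
    gps_on_s: float = 60.0
    gps_off_s: float = 240.0
    gps_hz: float = 1.0
    gps_noise_sd_m: float = 3.0
    accel_on_s: float = 10.0
    accel_off_s: float = 10.0
    accel_hz: float = 10.0
    idle_burst_keep: float = 0.02
    # gait
    cadence_hz: float = 1.8
    step_amplitude_g: float = 0.28
    accel_noise_g: float = 0.02
    # movement
    transit_speed_ms: float = 8.0
    walk_speed_ms: float = 1.3
    ambient_speed_ms: float = 2.0
    ambient_dwell_min_s: float = 120.0
    ambient_dwell_max_s: float = 600.0
    indoor_min_s: float = 2420.0   # indoor errand stops (GPS-silent middle)
    indoor_shoulder_s: float = 260.0
    ambient_hop_min_m: float = 60.0
    ambient_hop_max_m: float = 1200.0
    align_hops_to_gaps: bool = True  # move between ambient spots inside GPS off-windows
    # day-to-day structure
    night_start_h: float = 20.0
    night_end_h: float = 8.0
    visit_noise_sd: float = 0.10
    sigma_patient: float = 0.12
    sigma_day: float = 0.30
    day_loading: float = 0.7
    home_sigma_patient_h: float = 0.35
    home_sigma_day_h: float = 0.45
    home_day_loading: float = -0.65
    count_sigma_day: float = 0.12
    count_day_loading: float = 0.5
    home_min_h: float = 10.5
    home_max_h: float = 20.5
    # missingness / PROMs
    day_missing_prob: float = 0.10
    render_sensors: bool = True  # False: ground truth / PROMs only (fast)
    vas_response_prob: float = 0.52
    weekly_response_prob: dict = field(default_factory=lambda: dict(WEEKLY_RESPONSE))
    prom_links: dict = field(default_factory=lambda: dict(PROM_LINK_DEFAULTS))
    timezone: str = "Europe/Rome"
    first_surgery_date: str = "2023-04-03"

    def __post_init__(self):
        if self.n_anterior + self.n_posterior <= 0:
            raise ConfigError("cohort must contain patients")
        for name in ("gps_on_s", "gps_off_s", "accel_on_s", "accel_off_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for inst, (_, r, _, _) in self.prom_links.items():
            if not -1 < r < 1:
                raise ConfigError(f"target correlation for {inst} must lie in (-1, 1)")
        if not self.trajectories:
            self.trajectories = default_trajectories(self.n_anterior, self.n_posterior)
        t1_home = self.trajectory_mean("home_hours", "anterior", 1)
        if t1_home > 24 or self.trajectory_mean("home_hours", "posterior", 1) > 24:
            raise ConfigError("home-hours trajectory exceeds 24 h/day")

    @property
    def n_patients(self) -> int:
        return self.n_anterior + self.n_posterior

    def trajectory_mean(self, var: str, arm: str, day) -> np.ndarray | float:
        a, b = self.trajectories[var][arm]
        day = np.minimum(np.asarray(day, dtype=float), float(self.plateau_day))
        if var == "home_hours":
            return a + b * day
        return np.exp(a + b * day)


def default_trajectories(n_a: int = 6, n_p: int = 7,
                         pooled: dict | None = None) -> dict:
    """Per-arm (intercept, slope) calibrated to the pooled week targets."""
    pooled = pooled or POOLED_TARGETS
    out = {}
    for var, (t1, t5) in pooled.items():
        if var == "home_hours":
            arms = split_arms_delta(t1, t5, *HOME_DELTAS, n_a, n_p)
            out[var] = {arm: solve_linear_trajectory(*arms[arm]) for arm in arms}
        else:
            arms = split_arms_ratio(t1, t5, *ARM_RATIOS[var], n_a, n_p)
            out[var] = {arm: solve_log_trajectory(*arms[arm]) for arm in arms}
    return out


def paper_cohort_config(**overrides) -> CohortConfig:
    """The default study-scale cohort: 13 patients (6 anterior / 7
    posterior), 70-day follow-up, trajectories calibrated to the pooled
    week-1/week-5 targets."""
    return CohortConfig(**overrides)


# ---------------------------------------------------------------------------
# day plans
# ---------------------------------------------------------------------------

@dataclass
class Stay:
    place_id: str
    lat: float
    lon: float
    start: float  # local seconds from midnight
    end: float
    significant: bool = True
    indoor: bool = False  # no GPS fix except brief doorstep shoulders


@dataclass
class Transit:
    """Movement between stays: a time-stamped polyline plus the sub-windows
    walked on foot (step-generating)."""
    anchors: list  # [(t, lat, lon), ...] strictly increasing t
    walking: list = field(default_factory=list)  # [(t0, t1), ...]

    @property
    def start(self):
        return self.anchors[0][0]

    @property
    def end(self):
        return self.anchors[-1][0]

    def path_length_m(self) -> float:
        a = np.array([(p[1], p[2]) for p in self.anchors])
        if len(a) < 2:
            return 0.0
        return float(np.sum(haversine_m(a[:-1, 0], a[:-1, 1], a[1:, 0], a[1:, 1])))


@dataclass
class DayPlan:
    stays: list
    transits: list = field(default_factory=list)
    missing: bool = False

    def validate(self):
        ivals = [(s.start, s.end, "stay") for s in self.stays]
        ivals += [(t.start, t.end, "transit") for t in self.transits]
        ivals.sort()
        for (s0, e0, k0), (s1, e1, k1) in zip(ivals, ivals[1:]):
            if s1 < e0 - 1e-9:
                raise ScheduleError(
                    f"overlapping {k0}/{k1} intervals at {e0:.0f}/{s1:.0f}")
        for s in self.stays:
            if s.end <= s.start:
                raise ScheduleError("stay must have positive duration")


def stationary_day_plan(lat: float, lon: float, place_id: str = "home") -> DayPlan:
    return DayPlan(stays=[Stay(place_id, lat, lon, 0.0, 86400.0)])


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _offset(lat: float, lon: float, dx_m: float, dy_m: float) -> tuple[float, float]:
    return (lat + dy_m * DEG_M, lon + dx_m * DEG_M / math.cos(math.radians(lat)))


def _zigzag(lat0, lon0, lat1, lon1, extra_m: float, n_bends: int = 2):
    """Waypoints (excluding endpoints) of a shallow zigzag whose path exceeds
    the straight chord by extra_m; used to realize a planned transit length
    while keeping corner angles gentle (corner-cut losses across duty-cycle
    gaps stay small)."""
    chord = float(haversine_m(lat0, lon0, lat1, lon1))
    if extra_m <= 1.0 or chord < 50.0:
        return []
    m = max(2, int(n_bends))
    seg = chord / m
    # per-segment lateral offset h: each zig pair adds 2*(sqrt((seg/2)^2+h^2)-seg/2)
    want = extra_m / m
    h = math.sqrt(max((seg / 2.0 + want / 2.0) ** 2 - (seg / 2.0) ** 2, 0.0))
    ux = (lon1 - lon0), (lat1 - lat0)
    pts = []
    for j in range(1, m):
        f = j / m
        base_lat = lat0 + (lat1 - lat0) * f
        base_lon = lon0 + (lon1 - lon0) * f
        side = 1.0 if j % 2 == 1 else -1.0
        # perpendicular direction in planar meters
        dxm = (lon1 - lon0) * math.cos(math.radians(lat0)) / DEG_M
        dym = (lat1 - lat0) / DEG_M
        norm = math.hypot(dxm, dym) or 1.0
        px, py = -dym / norm, dxm / norm
        pts.append(_offset(base_lat, base_lon, side * h * px, side * h * py))
    return pts


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

@dataclass
class PatientGeography:
    home: tuple
    places: list          # [(lat, lon)] significant candidate places
    district: tuple       # center of the ambient-drift zone


def make_geography(i: int, cfg: CohortConfig, rng: np.random.Generator) -> PatientGeography:
    # patients spaced ~10 km apart; geometry is per patient, so spacing only
    # needs to avoid coordinate collisions
    home = (45.40 + 0.09 * i, 10.90 + 0.02 * (i % 3))
    places = []
    for j, r_km in enumerate(cfg.place_radii_km[: cfg.n_places]):
        ang = math.radians(90.0 * j + rng.uniform(-25, 25))
        r = r_km * 1000.0 * rng.uniform(0.92, 1.08)
        places.append(_offset(*home, r * math.cos(ang), r * math.sin(ang)))
    d_ang = rng.uniform(0, 2 * math.pi)
    district = _offset(*home, 220 * math.cos(d_ang), 220 * math.sin(d_ang))
    return PatientGeography(home=home, places=places, district=district)


def _too_close(lat, lon, keepout, min_m=120.0):
    for (la, lo) in keepout:
        if haversine_m(lat, lon, la, lo) < min_m:
            return True
    return False


def _ambient_chain(start, geo: PatientGeography, n_hops: int, hop_m: float,
                   rng: np.random.Generator):
    """Drifting chain of ambient dwell spots: gentle turns, reflected back
    toward the district center, kept >= 120 m from home and places."""
    keepout = [geo.home] + geo.places
    spots = []
    lat, lon = start
    heading = rng.uniform(0, 2 * math.pi)
    for _ in range(n_hops):
        for _attempt in range(12):
            d_home = haversine_m(lat, lon, *geo.district)
            if d_home > max(380.0, 1.6 * hop_m):
                # steer back toward the district
                dy = (geo.district[0] - lat) / DEG_M
                dx = (geo.district[1] - lon) * math.cos(math.radians(lat)) / DEG_M
                heading = math.atan2(dy, dx) + rng.uniform(-0.5, 0.5)
            else:
                heading += rng.uniform(-0.6, 0.6)
            cand = _offset(lat, lon, hop_m * math.cos(heading), hop_m * math.sin(heading))
            if not _too_close(*cand, keepout):
                break
            heading += rng.uniform(1.5, 3.5)
        lat, lon = cand
        spots.append((lat, lon))
    return spots


@dataclass
class DayTargets:
    distance_km: float
    home_hours: float
    n_visits: int
    visit_hours: float
    walking_s: float


def build_day_plan(targets: DayTargets, geo: PatientGeography,
                   cfg: CohortConfig, rng: np.random.Generator) -> DayPlan:
    """Construct an explicit day schedule realizing the day's latent targets
    as closely as the structural constraints allow.

    Away-from-home time not spent at significant places is filled with
    ambient drift (sub-15-min dwells hopping between spots); dwell lengths
    are solved from the exact travel-time budget so the realized home hours
    equal the day's target."""
    home_s = targets.home_hours * 3600.0
    night_s = (24.0 - cfg.night_start_h + cfg.night_end_h) * 3600.0
    extra_home = home_s - night_s  # negative: departures before 08:00
    u_split = rng.uniform(0.35, 0.65)
    # home blocks: [0, aw0] and [aw1, 86400]; the evening block always covers
    # [20:00, 24:00] so home detection stays anchored
    aw1 = cfg.night_start_h * 3600.0 - max(extra_home, 0.0) * (1.0 - u_split)
    aw0 = aw1 - (86400.0 - home_s)
    away = aw1 - aw0

    # --- choose visited places within the distance budget
    dist_m = targets.distance_km * 1000.0
    walk_d = targets.walking_s * cfg.walk_speed_ms
    n_visits = targets.n_visits
    # a small reserve covers the ambient connectors and minimum drift; the
    # rest of the distance budget is available for trips
    trip_budget = max(dist_m - walk_d - 900.0, 1150.0)
    chosen: list = []
    for j in rng.permutation(len(geo.places)):
        if len(chosen) >= n_visits:
            break
        trial = chosen + [int(j)]
        if _route_length(geo, trial) + walk_d <= trip_budget:
            chosen = trial
    if len(chosen) < n_visits:
        # fall back to the nearest remaining places so the day's count target
        # is preserved even when the distance draw is small
        by_dist = sorted(range(len(geo.places)),
                         key=lambda j: haversine_m(*geo.home, *geo.places[j]))
        for j in by_dist:
            if len(chosen) >= n_visits:
                break
            if j not in chosen:
                chosen.append(j)
    chosen.sort(key=lambda j: haversine_m(*geo.home, *geo.places[j]))
    n_visits = len(chosen)

    visit_s = np.maximum(rng.lognormal(0.0, cfg.visit_noise_sd, n_visits), 0.1) \
        * targets.visit_hours * 3600.0 if n_visits else np.zeros(0)
    visit_s = np.maximum(visit_s, 1260.0)  # each visit must qualify (>15 min)
    if n_visits and visit_s.sum() > 0.6 * away:
        visit_s *= 0.6 * away / visit_s.sum()
        visit_s = np.maximum(visit_s, 1080.0)

    route_pts = [geo.places[j] for j in chosen]
    g_core = 0.0
    prev = geo.home
    for p in route_pts:
        g_core += float(haversine_m(*prev, *p))
        prev = p

    # --- size the ambient drift from rough budgets, then solve dwell exactly
    rough_travel = (g_core + float(haversine_m(*prev, *geo.home))) / cfg.transit_speed_ms \
        + targets.walking_s
    amb_time = away - float(visit_s.sum()) - rough_travel
    chain_start = route_pts[-1] if route_pts else geo.district
    start_con = 0.0 if route_pts else float(haversine_m(*geo.home, *geo.district))
    end_con_est = float(haversine_m(*geo.district, *geo.home))

    amb_spots: list = []
    n_hops = n_out = n_indoor = 0
    amb_fast = False
    indoor_idx: set = set()
    if amb_time > 300.0:
        amb_budget = max(dist_m - walk_d - g_core - start_con - end_con_est, 0.0)
        # outdoor drift is sized by the distance budget; the remaining away
        # time is spent at indoor errand stops (no GPS fix inside), which
        # consume time without distance and never form pauses
        n_out_cap = max(int(amb_time // 400.0), 1)
        n_out = int(np.clip(round(amb_budget / 120.0), 1, n_out_cap))
        hop0 = float(np.clip(amb_budget / n_out, cfg.ambient_hop_min_m,
                             cfg.ambient_hop_max_m))
        hop_t0 = hop0 / (cfg.transit_speed_ms if hop0 > 160.0 else cfg.ambient_speed_ms)
        indoor_est = amb_time - n_out * (450.0 + hop_t0)
        n_indoor = 0 if indoor_est < cfg.indoor_min_s \
            else int(math.ceil(indoor_est / 5400.0))
        n_hops = n_out + n_indoor
        hop_m = float(np.clip(amb_budget / n_hops, cfg.ambient_hop_min_m,
                              cfg.ambient_hop_max_m))
        amb_fast = hop_m > 160.0
        amb_spots = _ambient_chain(chain_start, geo, n_hops, hop_m, rng)
        if n_indoor:
            step = n_hops / n_indoor
            indoor_idx = {min(int((k + 0.5) * step), n_hops - 1)
                          for k in range(n_indoor)}
            n_indoor = len(indoor_idx)
            n_out = n_hops - n_indoor

    # --- exact leg geometry
    waypoints = [geo.home] + route_pts + list(amb_spots) + [geo.home]
    is_ambient_leg = [False] * (len(route_pts)) + [True] * len(amb_spots) + [False]
    if not amb_spots and not route_pts:
        waypoints = [geo.home, geo.district, geo.home]
        is_ambient_leg = [False, False]
    leg_chords = [float(haversine_m(*a, *b)) for a, b in zip(waypoints, waypoints[1:])]
    realized = sum(leg_chords)
    detour_m = max(dist_m - walk_d - realized, 0.0)
    # spread detours over the non-ambient legs (zigzags need room)
    detour_legs = [i for i, (amb, c) in enumerate(zip(is_ambient_leg, leg_chords))
                   if not amb and c > 200.0]
    detour_per = detour_m / len(detour_legs) if detour_legs else 0.0
    leg_extra = [detour_per if i in detour_legs else 0.0
                 for i in range(len(leg_chords))]
    leg_len = [c + e for c, e in zip(leg_chords, leg_extra)]

    # exact travel time, with the step-generating walk carved out of the
    # first and last non-ambient legs
    walk_alloc = [0.0] * len(leg_len)
    walk_left_d = min(walk_d, 0.7 * (leg_len[0] + leg_len[-1]))
    if leg_len:
        w0 = min(walk_left_d / 2.0, 0.7 * leg_len[0])
        walk_alloc[0] = w0
        walk_alloc[-1] = min(walk_left_d - w0, 0.7 * leg_len[-1])
        if len(leg_len) == 1:
            walk_alloc = [min(walk_left_d, 0.7 * leg_len[0])]
    amb_leg_speed = cfg.transit_speed_ms if amb_fast else cfg.ambient_speed_ms
    t_travel = 0.0
    for L, w, amb in zip(leg_len, walk_alloc, is_ambient_leg):
        speed = amb_leg_speed if amb else cfg.transit_speed_ms
        t_travel += w / cfg.walk_speed_ms + max(L - w, 0.0) / speed

    dwell_total = away - float(visit_s.sum()) - t_travel
    dwell = 0.0
    indoor_dur = 0.0
    if n_hops:
        if n_indoor:
            indoor_dur = (dwell_total - 450.0 * n_out) / n_indoor
            if indoor_dur < cfg.indoor_min_s:
                # not enough time for the planned indoor stops; drop some
                keep = int(max((dwell_total - 300.0 * n_out) // cfg.indoor_min_s, 0))
                while len(indoor_idx) > keep:
                    indoor_idx.pop()
                n_indoor = len(indoor_idx)
                n_out = n_hops - n_indoor
                indoor_dur = cfg.indoor_min_s if n_indoor else 0.0
        if n_indoor and n_out:
            dwell = (dwell_total - n_indoor * indoor_dur) / n_out
            dwell = float(np.clip(dwell, cfg.ambient_dwell_min_s,
                                  cfg.ambient_dwell_max_s))
        elif n_indoor:
            indoor_dur = dwell_total / n_indoor
        else:
            dwell = float(np.clip(dwell_total / n_hops, cfg.ambient_dwell_min_s,
                                  cfg.ambient_dwell_max_s))
    # residual timing error goes into the visit stays (when present) so the
    # realized home block matches the target; otherwise it shifts the return
    resid = dwell_total - dwell * n_out - indoor_dur * n_indoor
    if not n_indoor:
        resid = dwell_total - dwell * n_hops
    if n_visits and abs(resid) > 1.0:
        adj = np.clip(visit_s + resid / n_visits, 1080.0, None)
        resid -= float(adj.sum() - visit_s.sum())
        visit_s = adj

    # --- assemble the timeline
    stays = [Stay("home", *geo.home, 0.0, aw0)]
    transits = []
    t = aw0
    cur = geo.home
    stay_meta = []  # aligned with legs: (dwell_s, significant, place_id)
    for k, j in enumerate(chosen):
        stay_meta.append((float(visit_s[k]), True, f"place_{j}"))
    jit = rng.uniform(-30.0, 30.0, len(amb_spots)) if amb_spots else []
    for si in range(len(amb_spots)):
        if si in indoor_idx:
            stay_meta.append((float(indoor_dur), False, f"ind_{si}"))
        else:
            stay_meta.append((max(dwell + jit[si], 60.0), False, f"amb_{si}"))
    if not amb_spots and not route_pts:
        # degenerate near-housebound day: one short errand, remainder at home
        stay_meta.append((float(np.clip(dwell_total, 60.0, 760.0)), False, "amb_0"))
    stay_meta.append((None, True, "home"))

    gps_period = cfg.gps_on_s + cfg.gps_off_s
    t_sched = aw0  # nominal departure grid; keeps alignment shifts unbiased

    def _align_departure(t_now: float, t_nom: float, dur_move: float) -> float:
        # depart inside the GPS off-window nearest the *nominal* departure
        # time (chord-based flight distance then captures the full hop);
        # targeting the nominal grid prevents shifts from accumulating into
        # a systematic early/late return home
        if not cfg.align_hops_to_gaps or dur_move > cfg.gps_off_s - 10.0:
            return t_now
        u = gps_period * round((t_nom - cfg.gps_on_s - 2.0) / gps_period) \
            + cfg.gps_on_s + 2.0
        prev = stays[-1]
        if prev.place_id.startswith("amb") and u - prev.start > 800.0:
            return t_now  # never stretch an ambient stay toward the 15-min mark
        if u < prev.start + 60.0 or u + dur_move > (u // gps_period) * gps_period \
                + gps_period or u + dur_move > 86000.0:
            return t_now
        prev.end = u
        return u

    dests = waypoints[1:]
    for i_leg, (dest, (dwell_s, sig, pid)) in enumerate(zip(dests, stay_meta)):
        extra = leg_extra[i_leg]
        way = _zigzag(*cur, *dest, extra,
                      n_bends=max(2, int((leg_chords[i_leg] + extra) // 2500) * 2)) \
            if extra > 1.0 else []
        pts = [cur] + way + [dest]
        seg_len = [float(haversine_m(*a, *b)) for a, b in zip(pts, pts[1:])]
        total_len = sum(seg_len)
        speed = amb_leg_speed if is_ambient_leg[i_leg] else cfg.transit_speed_ms
        walk_d_here = min(walk_alloc[i_leg], total_len)
        walk_here = walk_d_here / cfg.walk_speed_ms
        dur = walk_here + max(total_len - walk_d_here, 0.0) / speed
        if total_len <= 1.0:
            dur = max(dur, 1.0)
        if walk_d_here <= 0.0:
            t = _align_departure(t, t_sched, dur)
        anchors = [(t, cur[0], cur[1])]
        cum = 0.0
        walk_first = (i_leg == 0)
        for (a, b), L in zip(zip(pts, pts[1:]), seg_len):
            seg_t = _segment_time(cum, L, total_len, walk_d_here, walk_first,
                                  cfg.walk_speed_ms, speed)
            cum += L
            anchors.append((anchors[-1][0] + seg_t, b[0], b[1]))
        t_end = t + dur
        ts = np.array([a[0] for a in anchors])
        if ts[-1] > ts[0]:
            ts = t + (ts - ts[0]) * (dur / (ts[-1] - ts[0]))
        anchors = [(float(tt), a[1], a[2]) for tt, a in zip(ts, anchors)]
        walking_windows = []
        if walk_here > 0.5:
            if walk_first:
                walking_windows.append((t, t + walk_here))
            else:
                walking_windows.append((t_end - walk_here, t_end))
        transits.append(Transit(anchors=anchors, walking=walking_windows))
        t = t_end
        cur = dest
        t_sched += dur
        if dwell_s is not None:
            stays.append(Stay(pid, dest[0], dest[1], t, t + dwell_s,
                              significant=sig, indoor=pid.startswith("ind_")))
            t += dwell_s
            t_sched += dwell_s

    stays.append(Stay("home", *geo.home, max(t, aw0 + 1.0), 86400.0))
    plan = DayPlan(stays=stays, transits=transits)
    plan.validate()
    return plan


def _route_length(geo: PatientGeography, chosen: list) -> float:
    pts = [geo.home] + [geo.places[j] for j in sorted(
        chosen, key=lambda j: haversine_m(*geo.home, *geo.places[j]))] + [geo.home]
    return float(sum(haversine_m(*a, *b) for a, b in zip(pts, pts[1:])))


def _segment_time(cum: float, L: float, total: float, walk_d: float,
                  walk_first: bool, v_walk: float, v_ride: float) -> float:
    """Traversal time of a sub-segment [cum, cum+L] of a leg whose first (or
    last) walk_d meters are walked."""
    if walk_d <= 0:
        return L / v_ride
    if walk_first:
        w = max(min(cum + L, walk_d) - cum, 0.0)
    else:
        w0 = total - walk_d
        w = max(cum + L - max(cum, w0), 0.0)
    return w / v_walk + (L - w) / v_ride


# ---------------------------------------------------------------------------
# sensor rendering
# ---------------------------------------------------------------------------

def _plan_anchor_arrays(plan: DayPlan):
    pts = []
    for s in plan.stays:
        pts.append((s.start, s.lat, s.lon))
        pts.append((s.end, s.lat, s.lon))
    for tr in plan.transits:
        pts.extend(tr.anchors)
    pts.sort(key=lambda p: p[0])
    t = np.array([p[0] for p in pts])
    lat = np.array([p[1] for p in pts])
    lon = np.array([p[2] for p in pts])
    keep = np.concatenate([[True], np.diff(t) > 1e-9])
    return t[keep], lat[keep], lon[keep]


def ground_truth_row(plan: DayPlan, cfg: CohortConfig) -> dict:
    """Extractor-independent truth for one planned day."""
    dist_m = sum(tr.path_length_m() for tr in plan.transits)
    home_s = sum(s.end - s.start for s in plan.stays if s.place_id == "home")
    occ: dict[str, float] = {}
    for s in plan.stays:
        if s.significant:
            occ[s.place_id] = occ.get(s.place_id, 0.0) + (s.end - s.start)
    total = sum(occ.values())
    shares = np.array([v / total for v in occ.values()]) if total > 0 else np.zeros(0)
    walking_s = sum(e - b for tr in plan.transits for (b, e) in tr.walking)
    return {
        "distance_km": dist_m / 1000.0,
        "home_hours": home_s / 3600.0,
        "sig_loc_count": float(len(occ)),
        "sig_loc_entropy": entropy_nats(shares),
        "steps": cfg.cadence_hz * walking_s,
        "occupancy_shares": "|".join(f"{v:.12g}" for v in shares),
        "missing": plan.missing,
    }


def render_gps(plan: DayPlan, cfg: CohortConfig, day_epoch: float,
               rng: np.random.Generator) -> pd.DataFrame:
    """Duty-cycled GPS points for one day: points exist only inside
    on-windows; positions follow the plan's polyline plus isotropic noise."""
    if plan.missing:
        return pd.DataFrame(columns=["t", "lat", "lon", "accuracy"])
    period = cfg.gps_on_s + cfg.gps_off_s
    n_cycles = int(86400.0 // period)
    within = np.arange(0, cfg.gps_on_s, 1.0 / cfg.gps_hz)
    t_loc = (np.arange(n_cycles)[:, None] * period + within[None, :]).ravel()
    t_loc = t_loc[t_loc < 86400.0]
    # indoor stays have no GPS fix except brief doorstep shoulders
    sh = cfg.indoor_shoulder_s
    for s in plan.stays:
        if s.indoor and s.end - s.start > 2.0 * sh:
            t_loc = t_loc[(t_loc < s.start + sh) | (t_loc >= s.end - sh)]
    at, alat, alon = _plan_anchor_arrays(plan)
    lat = np.interp(t_loc, at, alat)
    lon = np.interp(t_loc, at, alon)
    sd_lat = cfg.gps_noise_sd_m * DEG_M
    sd_lon = cfg.gps_noise_sd_m * DEG_M / math.cos(math.radians(float(alat[0])))
    lat = lat + rng.normal(0.0, sd_lat, lat.shape)
    lon = lon + rng.normal(0.0, sd_lon, lon.shape)
    return pd.DataFrame({"t": day_epoch + t_loc, "lat": lat, "lon": lon,
                         "accuracy": np.round(np.abs(rng.normal(8.0, 3.0, lat.shape)) + 3.0, 1)})


def render_accel(plan: DayPlan, cfg: CohortConfig, day_epoch: float,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Duty-cycled accelerometer bursts.

    Bursts overlapping walking windows carry a cadence-frequency oscillation
    along the gravity axis; other materialized bursts are gravity plus noise.
    Idle bursts are subsampled at ``idle_burst_keep`` — they contribute zero
    steps, so daily counts are unaffected.
    """
    if plan.missing:
        return pd.DataFrame(columns=["t", "x", "y", "z"])
    period = cfg.accel_on_s + cfg.accel_off_s
    n_cycles = int(86400.0 // period)
    b_start = np.arange(n_cycles) * period
    walking = sorted((b, e) for tr in plan.transits for (b, e) in tr.walking)
    w_mask = np.zeros(n_cycles, dtype=bool)
    for (b, e) in walking:
        w_mask |= (b_start < e) & (b_start + cfg.accel_on_s > b)
    keep = w_mask | (rng.random(n_cycles) < cfg.idle_burst_keep)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return pd.DataFrame(columns=["t", "x", "y", "z"])
    within = np.arange(0, cfg.accel_on_s, 1.0 / cfg.accel_hz)
    t_loc = (b_start[idx][:, None] + within[None, :]).ravel()
    walk_frac = np.zeros(t_loc.shape)
    for (b, e) in walking:
        walk_frac += ((t_loc >= b) & (t_loc < e)).astype(float)
    osc = cfg.step_amplitude_g * np.sin(2 * np.pi * cfg.cadence_hz * t_loc) * (walk_frac > 0)
    mag = 1.0 + osc
    # random (per-day) device orientation; magnitude is orientation-invariant
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    noise = rng.normal(0.0, cfg.accel_noise_g / math.sqrt(3.0), (t_loc.size, 3))
    xyz = mag[:, None] * v[None, :] + noise
    return pd.DataFrame({"t": day_epoch + t_loc, "x": xyz[:, 0], "y": xyz[:, 1],
                         "z": xyz[:, 2]})


def simulate_patient_day(plan: DayPlan, cfg: CohortConfig, day_epoch: float,
                         rng: np.random.Generator):
    """Render one planned day -> (gps, accel, ground-truth row)."""
    plan.validate()
    truth = ground_truth_row(plan, cfg)
    gps = render_gps(plan, cfg, day_epoch, rng)
    accel = render_accel(plan, cfg, day_epoch, rng)
    return gps, accel, truth


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _patient_metas(cfg: CohortConfig, rng: np.random.Generator) -> list[PatientMeta]:
    metas = []
    sexes = (["F", "F"] + ["M"] * max(cfg.n_anterior - 2, 0))[: cfg.n_anterior] \
        + (["F"] + ["M"] * max(cfg.n_posterior - 1, 0))[: cfg.n_posterior]
    levels_pool = [1, 1, 1, 1, 2, 2, 2, 2, 2, 2, 3, 3, 4]
    instr_pool = [True] * 9 + [False] * 4
    base = pd.Timestamp(cfg.first_surgery_date)
    for i in range(cfg.n_patients):
        arm = "anterior" if i < cfg.n_anterior else "posterior"
        age = rng.normal(50, 6) if arm == "anterior" else rng.normal(67, 5)
        metas.append(PatientMeta(
            patient_id=f"P{i+1:02d}",
            age=float(np.clip(round(age), 30, 85)),
            sex=sexes[i], approach=arm,
            levels=int(levels_pool[i % len(levels_pool)]),
            instrumentation=bool(instr_pool[i % len(instr_pool)]),
            surgery_date=str((base + pd.Timedelta(days=2 * i)).date()),
            timezone=cfg.timezone,
        ))
    return metas


def _day_targets(cfg: CohortConfig, arm: str, day: int, u_pat: float,
                 u_home: float, rng: np.random.Generator,
                 visit_cache: dict, count_state: dict | None = None) -> DayTargets:
    z = rng.normal()

    def logmult(sigma, w):
        eps = w * z + math.sqrt(max(1 - w * w, 0.0)) * rng.normal()
        return math.exp(sigma * eps - sigma * sigma / 2.0)

    pat_mult = math.exp(cfg.sigma_patient * u_pat - cfg.sigma_patient ** 2 / 2.0)
    d_mean = cfg.trajectory_mean("distance_km", arm, day)
    s_mean = cfg.trajectory_mean("steps", arm, day)
    distance = d_mean * pat_mult * logmult(cfg.sigma_day, cfg.day_loading)
    steps_raw = s_mean * pat_mult * logmult(cfg.sigma_day, cfg.day_loading * 0.85)

    h_mean = cfg.trajectory_mean("home_hours", arm, day)
    eps_h = cfg.home_day_loading * z + math.sqrt(1 - cfg.home_day_loading ** 2) * rng.normal()
    home = float(np.clip(h_mean + cfg.home_sigma_patient_h * u_home
                         + cfg.home_sigma_day_h * eps_h,
                         cfg.home_min_h, cfg.home_max_h))

    key = (arm, day)
    if key not in visit_cache:
        c_mean = cfg.trajectory_mean("sig_loc_count", arm, day)
        lam = float(np.clip(c_mean - 1.0, 1e-6, cfg.n_places - 1e-6))
        e_target = cfg.trajectory_mean("sig_loc_entropy", arm, day)
        h_sd = math.hypot(cfg.home_sigma_patient_h, cfg.home_sigma_day_h)
        draws = _entropy_mc_draws(lam, cfg.n_places, h_mean, h_sd,
                                  cfg.home_min_h, cfg.home_max_h,
                                  cfg.count_sigma_day, cfg.visit_noise_sd)
        v_h = solve_visit_hours_mc(e_target, draws)
        visit_cache[key] = (lam, v_h)
    lam, v_h = visit_cache[key]
    lam_d = min(lam * logmult(cfg.count_sigma_day, cfg.count_day_loading),
                float(cfg.n_places))
    # error-diffusion integerization: visits follow a quasi-regular schedule
    # (people space errands out), giving the very low day-to-day count
    # dispersion this cohort is calibrated to; the carry accumulates the
    # fractional rate across a patient's days
    if count_state is not None:
        x = lam_d + count_state.get("carry", 0.0)
        n_visits = int(min(x, cfg.n_places))
        count_state["carry"] = x - n_visits
    else:
        n_visits = int(lam_d) + int(rng.random() < (lam_d - int(lam_d)))

    walking_s = 2.0 * steps_raw / cfg.cadence_hz  # 50% accel duty cycle
    return DayTargets(distance_km=float(distance), home_hours=home,
                      n_visits=n_visits, visit_hours=float(v_h),
                      walking_s=float(walking_s))


def simulate_cohort(cfg: CohortConfig, seed: int) -> CohortBundle:
    """Simulate the full cohort: sensors, ground truth and PROMs.

    Deterministic under a fixed seed (hierarchical bit generators per
    patient)."""
    root = np.random.SeedSequence(seed)
    meta_rng = np.random.default_rng(root.spawn(1)[0])
    metas = _patient_metas(cfg, meta_rng)
    patient_seeds = root.spawn(cfg.n_patients + 1)

    gps, accel = {}, {}
    truth_rows = []
    visit_cache: dict = {}
    for i, meta in enumerate(metas):
        rng = np.random.default_rng(patient_seeds[i])
        geo = make_geography(i, cfg, rng)
        u_pat = rng.normal()
        u_home = rng.normal()
        day0 = pd.Timestamp(meta.surgery_date, tz=meta.timezone)
        g_parts, a_parts = [], []
        count_state = {"carry": float(rng.uniform())}  # random schedule phase
        for day in range(1, cfg.follow_up_days + 1):
            day_epoch = (day0 + pd.Timedelta(days=day)).timestamp()
            targets = _day_targets(cfg, meta.approach, day, u_pat, u_home,
                                   rng, visit_cache, count_state)
            plan = build_day_plan(targets, geo, cfg, rng)
            plan.missing = bool(rng.random() < cfg.day_missing_prob)
            if cfg.render_sensors:
                g, a, truth = simulate_patient_day(plan, cfg, day_epoch, rng)
            else:
                g = pd.DataFrame(columns=["t", "lat", "lon", "accuracy"])
                a = pd.DataFrame(columns=["t", "x", "y", "z"])
                truth = ground_truth_row(plan, cfg)
            truth.update(patient_id=meta.patient_id, postop_day=day)
            truth_rows.append(truth)
            if len(g):
                g_parts.append(g)
            if len(a):
                a_parts.append(a)
        gps[meta.patient_id] = pd.concat(g_parts, ignore_index=True) if g_parts \
            else pd.DataFrame(columns=["t", "lat", "lon", "accuracy"])
        accel[meta.patient_id] = pd.concat(a_parts, ignore_index=True) if a_parts \
            else pd.DataFrame(columns=["t", "x", "y", "z"])

    truth = pd.DataFrame(truth_rows)
    cols = ["patient_id", "postop_day", "missing", "distance_km", "home_hours",
            "sig_loc_count", "sig_loc_entropy", "steps", "occupancy_shares"]
    truth = truth[cols]

    prom_rng = np.random.default_rng(patient_seeds[-1])
    proms = generate_proms(truth, metas, cfg, prom_rng)
    return CohortBundle(patients=metas, gps=gps, accel=accel, proms=proms,
                        ground_truth=truth)


def generate_proms(truth: pd.DataFrame, metas, cfg: CohortConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    """PROM responses linked linearly to true mobility.

    Daily VAS is a linear function of the same day's anchor variable;
    weekly mJOA/ODI/NDI are linear in the trailing 7-day mean ending on the
    response date.  Noise is set so the model-implied Pearson correlation
    equals the configured target (truncation/rounding to the native scale is
    second-order)."""
    meta_by_id = {m.patient_id: m for m in metas}
    rows = []
    t = truth.copy()

    for inst, (anchor, r, loc, scale) in cfg.prom_links.items():
        lo, hi = PROM_RANGES[inst]
        b = r * scale
        sig_e = scale * math.sqrt(max(1 - r * r, 1e-9))
        if inst == "VAS":
            x = t[anchor].to_numpy(dtype=float)
            z = (x - x.mean()) / (x.std() or 1.0)
            respond = rng.random(len(t)) < cfg.vas_response_prob
            score = np.clip(np.round(loc + b * z + rng.normal(0, sig_e, len(t))), lo, hi)
            for (pid, day, sc, rp) in zip(t["patient_id"], t["postop_day"], score, respond):
                if rp:
                    meta = meta_by_id[pid]
                    date = (pd.Timestamp(meta.surgery_date) + pd.Timedelta(days=int(day))).date()
                    rows.append((pid, str(date), inst, float(sc)))
        else:
            # trailing 7-day means at weekly response dates
            wk = t[t["postop_day"] % 7 == 0].copy()
            m = (t.assign(week=(t["postop_day"] - 1) // 7)
                 .groupby(["patient_id", "week"])[anchor].mean().rename("xm"))
            wk["week"] = (wk["postop_day"] - 1) // 7
            wk = wk.join(m, on=["patient_id", "week"])
            x = wk["xm"].to_numpy(dtype=float)
            z = (x - x.mean()) / (x.std() or 1.0)
            p_resp = cfg.weekly_response_prob.get(inst, 0.7)
            respond = rng.random(len(wk)) < p_resp
            score = np.clip(np.round(loc + b * z + rng.normal(0, sig_e, len(wk))), lo, hi)
            for (pid, day, sc, rp) in zip(wk["patient_id"], wk["postop_day"], score, respond):
                if rp:
                    meta = meta_by_id[pid]
                    date = (pd.Timestamp(meta.surgery_date) + pd.Timedelta(days=int(day))).date()
                    rows.append((pid, str(date), inst, float(sc)))
    return pd.DataFrame(rows, columns=["patient_id", "date", "instrument", "score"])


def ground_truth_summary(truth: pd.DataFrame, week: int) -> pd.Series:
    """Pooled per-variable mean of the ground truth over one post-operative
    week (days 7(w-1)+1 .. 7w)."""
    days = np.arange(7 * (week - 1) + 1, 7 * week + 1)
    sub = truth[truth["postop_day"].isin(days)]
    if len(sub) == 0:
        raise ValueError(f"week {week} is empty")
    return sub[["distance_km", "home_hours", "sig_loc_count",
                "sig_loc_entropy", "steps"]].mean()


def config_to_yaml_dict(cfg: CohortConfig) -> dict:
    d = asdict(cfg)
    d["trajectories"] = {k: {a: list(v) for a, v in arms.items()}
                         for k, arms in d["trajectories"].items()}
    d["place_radii_km"] = list(d["place_radii_km"])
    d["prom_links"] = {k: list(v) for k, v in d["prom_links"].items()}
    return json.loads(json.dumps(d))
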