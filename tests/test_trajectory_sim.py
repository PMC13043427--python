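"""Synthetic-cohort generator tests: day plans, sensors, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mobrec import trajectory_sim as ts
from mobrec.gps_features import entropy_nats, haversine_m

HOME = (45.40, 10.90)


def small_cfg(**kw):
    kw.setdefault("follow_up_days", 7)
    kw.setdefault("n_anterior", 1)
    kw.setdefault("n_posterior", 1)
    kw.setdefault("day_missing_prob", 0.0)
    return ts.paper_cohort_config(**kw)


# ---------------------------------------------------------------------------
# calibration solvers
# ---------------------------------------------------------------------------

def test_log_trajectory_closed_form():
    a, b = ts.solve_log_trajectory(3.0, 12.0)
    wk1 = np.mean(np.exp(a + b * np.arange(1, 8)))
    wk5 = np.mean(np.exp(a + b * np.arange(29, 36)))
    assert wk1 == pytest.approx(3.0, rel=1e-9)
    assert wk5 == pytest.approx(12.0, rel=1e-9)


def test_linear_trajectory_closed_form():
    a, b = ts.solve_linear_trajectory(14.63, 14.05)
    assert a + 4 * b == pytest.approx(14.63)
    assert a + 32 * b == pytest.approx(14.05)


def test_arm_split_preserves_pooled_mean():
    arms = ts.split_arms_ratio(2.0, 8.0, 1.5, 1.2, 6, 7)
    w1 = (6 * arms["anterior"][0] + 7 * arms["posterior"][0]) / 13
    w5 = (6 * arms["anterior"][1] + 7 * arms["posterior"][1]) / 13
    assert w1 == pytest.approx(2.0)
    assert w5 == pytest.approx(8.0)


def test_infeasible_config_rejected():
    with pytest.raises(ts.ConfigError):
        ts.CohortConfig(trajectories={
            **ts.default_trajectories(),
            "home_hours": {"anterior": (30.0, 0.0), "posterior": (30.0, 0.0)},
        })
    with pytest.raises(ts.ConfigError):
        ts.solve_log_trajectory(-1.0, 2.0)


# ---------------------------------------------------------------------------
# day plans and per-day simulation
# ---------------------------------------------------------------------------

def test_stationary_home_day_truth():
    cfg = small_cfg()
    plan = ts.stationary_day_plan(*HOME)
    rng = np.random.default_rng(0)
    gps, accel, truth = ts.simulate_patient_day(plan, cfg, 1.68e9, rng)
    assert truth["distance_km"] == 0.0
    assert truth["home_hours"] == 24.0
    assert truth["sig_loc_entropy"] == 0.0
    assert truth["steps"] == 0.0
    assert truth["sig_loc_count"] == 1
    # all GPS points within noise of home
    d = haversine_m(gps["lat"], gps["lon"], *HOME)
    assert np.quantile(d, 0.99) < 5 * cfg.gps_noise_sd_m


def test_walk_visit_walk_day_truth():
    """Walk 1 km to place B, stay 2 h, walk back: distance 2 km and
    steps = cadence x 3600 s of walking."""
    cfg = small_cfg()
    b = (HOME[0] + 1000.0 / 111194.9, HOME[1])
    t0, t1 = 9 * 3600.0, 9 * 3600 + 1800.0
    t2, t3 = t1 + 7200.0, t1 + 7200 + 1800.0
    out = ts.Transit(anchors=[(t0, *HOME), (t1, *b)], walking=[(t0, t1)])
    back = ts.Transit(anchors=[(t2, *b), (t3, *HOME)], walking=[(t2, t3)])
    plan = ts.DayPlan(
        stays=[ts.Stay("home", *HOME, 0.0, t0),
               ts.Stay("place_b", *b, t1, t2),
               ts.Stay("home", *HOME, t3, 86400.0)],
        transits=[out, back])
    rng = np.random.default_rng(0)
    _, accel, truth = ts.simulate_patient_day(plan, cfg, 1.68e9, rng)
    assert truth["distance_km"] == pytest.approx(2.0, rel=1e-3)
    assert truth["steps"] == pytest.approx(cfg.cadence_hz * 3600.0)
    assert truth["sig_loc_count"] == 2
    shares = np.array([float(x) for x in truth["occupancy_shares"].split("|")])
    assert truth["sig_loc_entropy"] == pytest.approx(entropy_nats(shares))


def test_overlapping_stays_rejected():
    plan = ts.DayPlan(stays=[ts.Stay("home", *HOME, 0.0, 4000.0),
                             ts.Stay("b", HOME[0] + 0.01, HOME[1], 3000.0, 5000.0)])
    with pytest.raises(ts.ScheduleError):
        plan.validate()


def test_total_missingness_empty_streams():
    cfg = small_cfg(day_missing_prob=1.0)
    b = ts.simulate_cohort(cfg, 3)
    assert all(len(df) == 0 for df in b.gps.values())
    assert all(len(df) == 0 for df in b.accel.values())
    assert b.ground_truth["missing"].all()


def test_gps_points_only_in_on_windows():
    cfg = small_cfg(follow_up_days=2)
    b = ts.simulate_cohort(cfg, 5)
    meta = b.patients[0]
    gps = b.gps[meta.patient_id]
    day0 = pd.Timestamp(meta.surgery_date, tz=meta.timezone).timestamp() + 86400
    phase = (gps["t"] - day0) % (cfg.gps_on_s + cfg.gps_off_s)
    assert (phase < cfg.gps_on_s).all()


def test_seed_determinism_byte_identical():
    cfg = small_cfg(follow_up_days=3)
    b1 = ts.simulate_cohort(cfg, 11)
    b2 = ts.simulate_cohort(cfg, 11)
    for pid in b1.patient_ids:
        pd.testing.assert_frame_equal(b1.gps[pid], b2.gps[pid])
        pd.testing.assert_frame_equal(b1.accel[pid], b2.accel[pid])
    pd.testing.assert_frame_equal(b1.ground_truth, b2.ground_truth)
    pd.testing.assert_frame_equal(b1.proms, b2.proms)


def test_truth_entropy_reproduced_by_feature_formula():
    """Generator entropy always equals entropy_nats applied to the stored
    ground-truth share vector (the two modules share no code path here)."""
    b = ts.simulate_cohort(small_cfg(follow_up_days=10, render_sensors=False), 7)
    for _, r in b.ground_truth.iterrows():
        shares = np.array([float(x) for x in r["occupancy_shares"].split("|")]) \
            if r["occupancy_shares"] else np.zeros(0)
        assert r["sig_loc_entropy"] == pytest.approx(entropy_nats(shares), abs=1e-9)


def test_distance_and_steps_iff_movement():
    """distance = 0 iff no transit windows; steps = 0 iff no walking windows."""
    cfg = small_cfg()
    plan = ts.stationary_day_plan(*HOME)
    truth = ts.ground_truth_row(plan, cfg)
    assert truth["distance_km"] == 0.0 and truth["steps"] == 0.0
    rng = np.random.default_rng(2)
    geo = ts.make_geography(0, cfg, rng)
    vc = {}
    for _ in range(10):
        tg = ts._day_targets(cfg, "anterior", 3, 0.0, 0.0, rng, vc)
        p = ts.build_day_plan(tg, geo, cfg, rng)
        tr = ts.ground_truth_row(p, cfg)
        has_transit = len(p.transits) > 0 and tr["distance_km"] > 0
        has_walk = any(t.walking for t in p.transits)
        assert (tr["distance_km"] > 0) == has_transit
        assert (tr["steps"] > 0) == has_walk


def test_null_slopes_week_means_equal():
    """With all slopes 0, week-1 and week-5 ground-truth means agree; a
    two-sample t-test on patient week means fails to reject at alpha=0.01."""
    flat = {}
    for var, (t1, _) in ts.POOLED_TARGETS.items():
        if var == "home_hours":
            arms = ts.split_arms_delta(t1, t1, -0.8, -0.8, 50, 50)
            flat[var] = {a: ts.solve_linear_trajectory(*arms[a]) for a in arms}
        else:
            arms = ts.split_arms_ratio(t1, t1, 1.2, 1.2, 50, 50)
            flat[var] = {a: ts.solve_log_trajectory(*arms[a]) for a in arms}
    cfg = ts.paper_cohort_config(n_anterior=50, n_posterior=50, follow_up_days=35,
                                 trajectories=flat, day_missing_prob=0.0,
                                 render_sensors=False)
    b = ts.simulate_cohort(cfg, 17)
    gt = b.ground_truth
    wk1 = gt[gt.postop_day.between(1, 7)].groupby("patient_id")["distance_km"].mean()
    wk5 = gt[gt.postop_day.between(29, 35)].groupby("patient_id")["distance_km"].mean()
    p = stats.ttest_ind(wk1, wk5).pvalue
    assert p > 0.01


def test_zero_prom_linkage_gives_null_correlation():
    """A PROM with linkage coefficient 0 is uncorrelated with every mobility
    variable (|r| < 0.1 at n ~ hundreds of days)."""
    links = dict(ts.PROM_LINK_DEFAULTS)
    links["NDI"] = ("distance_km", 0.0, 24.0, 11.0)
    cfg = ts.paper_cohort_config(prom_links=links, day_missing_prob=0.0,
                                 render_sensors=False,
                                 weekly_response_prob={"mJOA": 0.7, "ODI": 0.7, "NDI": 1.0})
    b = ts.simulate_cohort(cfg, 23)
    gt = b.ground_truth.assign(week=(b.ground_truth.postop_day - 1) // 7)
    wm = gt.groupby(["patient_id", "week"])[["distance_km", "steps"]].mean().reset_index()
    ndi = b.proms[b.proms.instrument == "NDI"].copy()
    sd = {m.patient_id: m.surgery_date for m in b.patients}
    ndi["day"] = [(pd.Timestamp(d) - pd.Timestamp(sd[p])).days
                  for p, d in zip(ndi.patient_id, ndi.date)]
    ndi["week"] = (ndi.day - 1) // 7
    m = ndi.merge(wm, on=["patient_id", "week"])
    for var in ("distance_km", "steps"):
        r = np.corrcoef(m["score"], m[var])[0, 1]
        assert abs(r) < 0.15  # ~130 weekly pairs; null r concentrates near 0


def test_ground_truth_summary_oracle():
    cfg = small_cfg(follow_up_days=7, render_sensors=False)
    b = ts.simulate_cohort(cfg, 31)
    s = ts.ground_truth_summary(b.ground_truth, 1)
    # brute-force recomputation
    sub = b.ground_truth[b.ground_truth.postop_day.between(1, 7)]
    assert s["distance_km"] == pytest.approx(sub["distance_km"].mean())
    with pytest.raises(ValueError):
        ts.ground_truth_summary(b.ground_truth, 5)


def test_calibration_week_means_within_study_bands():
    """Over seed replicates, ground-truth week means fall inside the printed
    95% CIs in at least 80% of cases per variable (steps compared on the
    duty-cycled counting scale)."""
    bands = {
        "distance_km": ((2.34, 3.73), (12.17, 15.60)),
        "home_hours": ((13.62, 15.64), (13.13, 14.98)),
        "sig_loc_count": ((1.26, 1.40), (2.28, 2.61)),
        "sig_loc_entropy": ((0.08, 0.12), (0.23, 0.29)),
        "steps": ((90.70, 126.96), (222.88, 277.13)),
    }
    cfg = ts.paper_cohort_config(follow_up_days=35, day_missing_prob=0.0,
                                 render_sensors=False)
    duty = cfg.accel_on_s / (cfg.accel_on_s + cfg.accel_off_s)
    hits = {v: 0 for v in bands}
    n_rep = 20
    for seed in range(n_rep):
        b = ts.simulate_cohort(cfg, 9000 + seed)
        s1 = ts.ground_truth_summary(b.ground_truth, 1)
        s5 = ts.ground_truth_summary(b.ground_truth, 5)
        for var, (b1, b5) in bands.items():
            x1, x5 = s1[var], s5[var]
            if var == "steps":
                x1, x5 = x1 * duty, x5 * duty
            if b1[0] <= x1 <= b1[1] and b5[0] <= x5 <= b5[1]:
                hits[var] += 1
    for var, h in hits.items():
        assert h >= 0.8 * n_rep, f"{var}: only {h}/{n_rep} replicates in band"
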