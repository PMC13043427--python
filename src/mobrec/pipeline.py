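"""End-to-end orchestration: raw traces -> daily summaries -> analytic
dataset -> statistical results.

The stages mirror the CLI subcommands (`extract`, `preprocess`, `analyze`)
but operate on in-memory cohort bundles so they can be chained without CSV
round-trips.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import accel_features, analysis, gps_features, preprocess
from .io_config import MOBILITY_VARS, CohortBundle, RunConfig

log = logging.getLogger("mobrec")


def _local_days(t_epoch: np.ndarray, tz: str, surgery_date: str) -> np.ndarray:
    """Post-operative day index (surgery date = day 0) of each timestamp,
    computed at local midnights."""
    ts = pd.to_datetime(pd.Series(t_epoch), unit="s", utc=True).dt.tz_convert(tz)
    d0 = pd.Timestamp(surgery_date, tz=tz)
    return (ts.dt.normalize() - d0).dt.days.to_numpy()


def extract_patient(meta, gps: pd.DataFrame, accel: pd.DataFrame,
                    config: RunConfig, seed: int = 0,
                    collect_artifacts: bool = False):
    """All daily summaries for one patient.

    Pauses and flights are segmented per local day; significant locations are
    clustered once per patient over the whole follow-up and home is detected
    from the nightly windows.  A day whose GPS on-window coverage falls below
    ``min_onwindow_fraction`` has missing GPS fields; a day with no
    accelerometer bursts has missing steps.
    """
    artifacts = {}
    day_points: dict[int, pd.DataFrame] = {}
    if len(gps):
        days = _local_days(gps["t"].to_numpy(), meta.timezone, meta.surgery_date)
        for d in np.unique(days):
            if d >= 1:
                day_points[int(d)] = gps[days == d]

    pauses_by_day = {}
    for d, pts in day_points.items():
        pauses_by_day[d] = gps_features.segment_pauses(
            pts, config.pause_radius_m, config.min_pause_s, config.max_gap_s)
    all_pauses = (pd.concat(pauses_by_day.values(), ignore_index=True)
                  if pauses_by_day else pd.DataFrame(columns=gps_features.PAUSE_COLUMNS))

    sig_locs = gps_features.find_significant_locations(
        all_pauses, config.sig_loc_min_pause_s, config.sig_loc_separation_m, seed)
    home = None
    if len(sig_locs):
        sig_locs = gps_features.detect_home(sig_locs, all_pauses, meta.timezone,
                                            config.sig_loc_separation_m)
        home = sig_locs[sig_locs["is_home"]].iloc[0]

    steps_by_day = {}
    if len(accel):
        adays = _local_days(accel["t"].to_numpy(), meta.timezone, meta.surgery_date)
        params = accel_features.StepParams(
            config.bandpass_low, config.bandpass_high,
            config.peak_threshold_g, config.min_step_interval_s)
        for d in np.unique(adays):
            if d >= 1:
                steps_by_day[int(d)] = accel_features.daily_steps(
                    accel[adays == d], params,
                    extrapolate=config.extrapolate_steps,
                    on_s=config.accel_on_s,
                    period_s=config.accel_on_s + config.accel_off_s)

    n_windows = int(86400.0 // (config.gps_on_s + config.gps_off_s))
    rows = []
    flights_frames = []
    for d in sorted(set(day_points) | set(steps_by_day)):
        pts = day_points.get(d, pd.DataFrame(columns=["t", "lat", "lon"]))
        covered = 0
        if len(pts):
            t0 = pts["t"].to_numpy()
            period = config.gps_on_s + config.gps_off_s
            covered = len(np.unique(((t0 - t0.min()) // period).astype(int)))
        has_gps = covered >= config.min_onwindow_fraction * n_windows
        if has_gps and home is not None:
            day_pauses = pauses_by_day.get(d, pd.DataFrame(columns=gps_features.PAUSE_COLUMNS))
            flights = gps_features.extract_flights(
                pts, day_pauses, config.heading_change_deg,
                config.min_vertex_m, config.max_gap_s)
            if collect_artifacts and len(flights):
                flights_frames.append(flights.assign(postop_day=d))
            summary = gps_features.summarize_day(
                flights, day_pauses, sig_locs, home["lat"], home["lon"],
                config.sig_loc_separation_m, has_gps=True)
        else:
            summary = gps_features.summarize_day(
                pd.DataFrame(columns=gps_features.FLIGHT_COLUMNS),
                pd.DataFrame(columns=gps_features.PAUSE_COLUMNS),
                sig_locs, np.nan, np.nan, has_gps=False)
        summary.update(patient_id=meta.patient_id, postop_day=d,
                       steps=steps_by_day.get(d, np.nan))
        rows.append(summary)

    out = pd.DataFrame(rows, columns=["patient_id", "postop_day"] + MOBILITY_VARS)
    if collect_artifacts:
        artifacts = {
            "pauses": all_pauses,
            "flights": (pd.concat(flights_frames, ignore_index=True)
                        if flights_frames else pd.DataFrame(columns=gps_features.FLIGHT_COLUMNS)),
            "significant_locations": sig_locs,
        }
        return out, artifacts
    return out


def extract_daily_summaries(bundle: CohortBundle, config: RunConfig | None = None,
                            seed: int = 0) -> pd.DataFrame:
    """Daily-summary table for a whole cohort bundle."""
    config = config or RunConfig()
    parts = []
    for meta in bundle.patients:
        parts.append(extract_patient(meta, bundle.gps.get(meta.patient_id),
                                     bundle.accel.get(meta.patient_id),
                                     config, seed=seed))
        log.info("extracted %s", meta.patient_id)
    out = pd.concat(parts, ignore_index=True)
    return out[out["postop_day"] >= 1].reset_index(drop=True)


def preprocess_summaries(summaries: pd.DataFrame, bundle: CohortBundle,
                         config: RunConfig | None = None):
    """Run the cleaning ladder and attach the approach covariate."""
    config = config or RunConfig()
    approaches = {m.patient_id: m.approach for m in bundle.patients}
    dataset, report = preprocess.run_ladder(
        summaries, config, approaches=approaches,
        patients=[m.patient_id for m in bundle.patients])
    dataset.data["approach"] = dataset.data["patient_id"].map(approaches)
    return dataset, report


def analyze_dataset(dataset, bundle: CohortBundle, config: RunConfig | None = None,
                    with_curves: bool = True) -> dict:
    """Objectives 1-3 on an analytic dataset."""
    config = config or RunConfig()
    results = {"week_comparison": analysis.week_comparison(dataset)}
    results["glm_fits"] = analysis.fit_all_glms(dataset, config.gamma_zero_offset)
    if bundle.proms is not None and len(bundle.proms):
        surgery_dates = {m.patient_id: m.surgery_date for m in bundle.patients}
        results["correlations"] = analysis.correlate_proms(
            dataset, bundle.proms, surgery_dates, config.fdr_method)
        if with_curves:
            results["curves"] = analysis.relationship_curves(
                dataset, bundle.proms, surgery_dates)
    return results


def run_pipeline(bundle: CohortBundle, config: RunConfig | None = None,
                 seed: int = 0, with_curves: bool = False) -> dict:
    """extract -> preprocess -> analyze on an in-memory cohort."""
    config = config or RunConfig()
    summaries = extract_daily_summaries(bundle, config, seed=seed)
    dataset, report = preprocess_summaries(summaries, bundle, config)
    results = analyze_dataset(dataset, bundle, config, with_curves=with_curves)
    results["daily_summaries"] = summaries
    results["analytic"] = dataset
    results["cleaning_report"] = report
    return results
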