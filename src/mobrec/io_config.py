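"""CSV schemas, run configuration and cohort loading.

Raw sensor exports follow the Beiwe raw-export column style (``timestamp,
UTC time, latitude, longitude, altitude, accuracy``) but only the columns the
pipeline needs are required; extra columns are ignored and malformed rows are
dropped with a logged count (sensor exports are dirty — sparse patients are
handled downstream by the 50%-missingness rule, not at ingest).

Timestamps are stored internally as UTC epoch seconds; day boundaries are
computed in each patient's IANA timezone because "over the course of a day"
is a local-time concept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("mobrec")

MOBILITY_VARS = ["distance_km", "home_hours", "sig_loc_count", "sig_loc_entropy", "steps"]
PROM_INSTRUMENTS = {"VAS": (0, 10), "mJOA": (0, 18), "ODI": (0, 100), "NDI": (0, 100)}

GPS_COLUMN_ALIASES = {
    "timestamp": "t", "t": "t", "time": "t", "utc time": "t_iso",
    "latitude": "lat", "lat": "lat", "longitude": "lon", "lon": "lon",
    "accuracy": "accuracy",
}
ACCEL_COLUMN_ALIASES = {
    "timestamp": "t", "t": "t", "utc time": "t_iso",
    "x": "x", "y": "y", "z": "z",
    "accelerometer x": "x", "accelerometer y": "y", "accelerometer z": "z",
}


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class IntegrityError(ValueError):
    """Cross-file referential integrity violated."""


@dataclass
class PatientMeta:
    patient_id: str
    age: float
    sex: str
    approach: str  # anterior | posterior
    levels: int = 1
    instrumentation: bool = True
    surgery_date: str = "2023-04-03"  # ISO calendar date
    timezone: str = "Europe/Rome"

    def __post_init__(self):
        if self.approach not in ("anterior", "posterior"):
            raise ValueError(f"approach must be anterior|posterior, got {self.approach!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F|M, got {self.sex!r}")


@dataclass
class RunConfig:
    """Pipeline thresholds; defaults house the study constants
    (15-min/50-m significant locations, 70-day censoring, 50% missingness
    rule, MICE with m=5 over <=50 iterations)."""
    # GPS segmentation
    pause_radius_m: float = 50.0
    min_pause_s: float = 300.0
    sig_loc_min_pause_s: float = 900.0
    sig_loc_separation_m: float = 50.0
    heading_change_deg: float = 30.0
    min_vertex_m: float = 15.0
    max_gap_s: float = 1800.0
    accuracy_max_m: float | None = None  # optionally drop low-accuracy points
    min_onwindow_fraction: float = 0.1  # below this, the GPS day is missing
    gps_on_s: float = 60.0
    gps_off_s: float = 240.0
    # steps
    bandpass_low: float = 0.5
    bandpass_high: float = 3.0
    peak_threshold_g: float = 0.1
    min_step_interval_s: float = 0.3
    extrapolate_steps: bool = False
    accel_on_s: float = 10.0
    accel_off_s: float = 10.0
    # cleaning ladder
    censor_day: int = 70
    missing_fraction_threshold: float = 0.5
    mice_m: int = 5
    mice_iterations: int = 50
    mice_seed: int = 20230403
    outlier_rule: str = "tukey"
    outlier_k: float = 3.0
    log_variables: tuple = ("distance_km", "steps", "sig_loc_entropy")
    fdr_method: str = "fdr_bh"
    gamma_zero_offset: float = 0.01

    def __post_init__(self):
        for name in ("pause_radius_m", "min_pause_s", "sig_loc_min_pause_s",
                     "sig_loc_separation_m", "heading_change_deg", "min_vertex_m",
                     "max_gap_s", "peak_threshold_g", "min_step_interval_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.missing_fraction_threshold < 1:
            raise ValueError("missing_fraction_threshold must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            log.warning("ignoring unknown config keys: %s", sorted(unknown))
        if "log_variables" in known:
            known["log_variables"] = tuple(known["log_variables"])
        return cls(**known)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["log_variables"] = list(d["log_variables"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _normalize_columns(df: pd.DataFrame, aliases: dict) -> pd.DataFrame:
    ren = {}
    for c in df.columns:
        key = c.strip().lower()
        if key in aliases:
            ren[c] = aliases[key]
    return df.rename(columns=ren)


def _coerce_epoch_seconds(s: pd.Series) -> pd.Series:
    v = pd.to_numeric(s, errors="coerce")
    # Beiwe exports use epoch milliseconds; heuristically rescale
    big = v > 1e11
    v = v.where(~big, v / 1000.0)
    return v


def read_gps_csv(path, accuracy_max_m: float | None = None) -> pd.DataFrame:
    """Read one raw GPS trace CSV -> DataFrame[t, lat, lon, accuracy].

    Rows are sorted by time, duplicate timestamps keep the first row, and
    malformed rows (non-numeric or out-of-range coordinates) are dropped with
    a logged count.  An empty file yields an empty frame with a warning.
    """
    df = pd.read_csv(path)
    df = _normalize_columns(df, GPS_COLUMN_ALIASES)
    required = {"t", "lat", "lon"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required GPS columns {sorted(missing)}")
    if len(df) == 0:
        log.warning("%s: empty GPS file", path)
        return pd.DataFrame(columns=["t", "lat", "lon", "accuracy"])
    n0 = len(df)
    out = pd.DataFrame({
        "t": _coerce_epoch_seconds(df["t"]),
        "lat": pd.to_numeric(df["lat"], errors="coerce"),
        "lon": pd.to_numeric(df["lon"], errors="coerce"),
        "accuracy": pd.to_numeric(df["accuracy"], errors="coerce")
        if "accuracy" in df.columns else np.nan,
    })
    ok = (out["t"].notna() & out["lat"].notna() & out["lon"].notna()
          & out["lat"].between(-90, 90) & out["lon"].between(-180, 180))
    out = out[ok]
    if accuracy_max_m is not None:
        out = out[~(out["accuracy"] > accuracy_max_m)]
    out = out.sort_values("t", kind="mergesort").drop_duplicates("t", keep="first")
    dropped = n0 - len(out)
    if dropped:
        log.info("%s: dropped %d malformed/duplicate GPS rows", path, dropped)
    return out.reset_index(drop=True)


def read_accel_csv(path) -> pd.DataFrame:
    """Read one raw accelerometer CSV -> DataFrame[t, x, y, z] (g units)."""
    df = pd.read_csv(path)
    df = _normalize_columns(df, ACCEL_COLUMN_ALIASES)
    missing = {"t", "x", "y", "z"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required accelerometer columns {sorted(missing)}")
    if len(df) == 0:
        log.warning("%s: empty accelerometer file", path)
        return pd.DataFrame(columns=["t", "x", "y", "z"])
    n0 = len(df)
    out = pd.DataFrame({"t": _coerce_epoch_seconds(df["t"])})
    for c in ("x", "y", "z"):
        out[c] = pd.to_numeric(df[c], errors="coerce")
    out = out.dropna()
    out = out[np.isfinite(out[["x", "y", "z"]]).all(axis=1)]
    out = out.sort_values("t", kind="mergesort").drop_duplicates("t", keep="first")
    if n0 - len(out):
        log.info("%s: dropped %d malformed accelerometer rows", path, n0 - len(out))
    return out.reset_index(drop=True)


def read_patients_csv(path) -> list[PatientMeta]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = {"patient_id", "age", "sex", "approach", "surgery_date"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing patient columns {sorted(missing)}")
    metas = []
    for _, r in df.iterrows():
        metas.append(PatientMeta(
            patient_id=str(r["patient_id"]), age=float(r["age"]), sex=str(r["sex"]),
            approach=str(r["approach"]),
            levels=int(r.get("levels", 1) if pd.notna(r.get("levels", 1)) else 1),
            instrumentation=bool(r.get("instrumentation", True)),
            surgery_date=str(r["surgery_date"]),
            timezone=str(r.get("timezone", "Europe/Rome")),
        ))
    return metas


def read_proms_csv(path, known_patients=None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = {"patient_id", "date", "instrument", "score"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing PROM columns {sorted(missing)}")
    if known_patients is not None:
        unknown = set(df["patient_id"]) - set(known_patients)
        if unknown:
            raise IntegrityError(
                f"proms reference unknown patient_id(s): {sorted(unknown)}")
    bad = []
    for inst, (lo, hi) in PROM_INSTRUMENTS.items():
        m = df["instrument"] == inst
        bad.append(m & ~df["score"].between(lo, hi))
    bad_any = np.logical_or.reduce(bad) if bad else np.zeros(len(df), bool)
    if bad_any.any():
        log.warning("dropping %d PROM rows outside instrument scales", int(bad_any.sum()))
        df = df[~bad_any]
    return df.reset_index(drop=True)


@dataclass
class CohortBundle:
    """Everything the pipeline needs for one cohort."""
    patients: list  # of PatientMeta
    gps: dict = field(default_factory=dict)    # patient_id -> DataFrame[t,lat,lon,accuracy]
    accel: dict = field(default_factory=dict)  # patient_id -> DataFrame[t,x,y,z]
    proms: pd.DataFrame | None = None
    ground_truth: pd.DataFrame | None = None   # present for simulated cohorts

    @property
    def patient_ids(self):
        return [p.patient_id for p in self.patients]


def read_cohort(directory) -> CohortBundle:
    """Load a cohort directory: patients.csv, proms.csv and per-patient
    gps/<id>.csv and accel/<id>.csv files.  Patients without a sensor file
    get an empty stream (with a warning); PROMs referencing unknown patients
    raise an integrity error."""
    directory = Path(directory)
    patients = read_patients_csv(directory / "patients.csv")
    ids = [p.patient_id for p in patients]
    proms_path = directory / "proms.csv"
    proms = read_proms_csv(proms_path, known_patients=ids) if proms_path.exists() else None
    gps, accel = {}, {}
    for pid in ids:
        gp = directory / "gps" / f"{pid}.csv"
        ap = directory / "accel" / f"{pid}.csv"
        if gp.exists():
            gps[pid] = read_gps_csv(gp)
        else:
            log.warning("patient %s has no GPS file", pid)
            gps[pid] = pd.DataFrame(columns=["t", "lat", "lon", "accuracy"])
        if ap.exists():
            accel[pid] = read_accel_csv(ap)
        else:
            log.warning("patient %s has no accelerometer file", pid)
            accel[pid] = pd.DataFrame(columns=["t", "x", "y", "z"])
    gt_path = directory / "ground_truth.csv"
    gt = pd.read_csv(gt_path, dtype={"patient_id": str}) if gt_path.exists() else None
    return CohortBundle(patients=patients, gps=gps, accel=accel, proms=proms,
                        ground_truth=gt)


def write_cohort(bundle: CohortBundle, directory) -> None:
    """Write a cohort bundle in the on-disk layout `read_cohort` expects."""
    directory = Path(directory)
    (directory / "gps").mkdir(parents=True, exist_ok=True)
    (directory / "accel").mkdir(parents=True, exist_ok=True)
    pd.DataFrame([asdict(p) for p in bundle.patients]).to_csv(
        directory / "patients.csv", index=False)
    if bundle.proms is not None:
        bundle.proms.to_csv(directory / "proms.csv", index=False)
    for pid in bundle.patient_ids:
        bundle.gps[pid].to_csv(directory / "gps" / f"{pid}.csv", index=False)
        bundle.accel[pid].to_csv(directory / "accel" / f"{pid}.csv", index=False)
    if bundle.ground_truth is not None:
        bundle.ground_truth.to_csv(directory / "ground_truth.csv", index=False)


def write_daily_summaries(rows: pd.DataFrame, path) -> None:
    """Write the daily-summary table; one row per (patient_id, postop_day)."""
    if len(rows) == 0:
        raise ValueError("daily-summary table is empty")
    dup = rows.duplicated(subset=["patient_id", "postop_day"])
    if dup.any():
        raise ValueError("duplicate (patient_id, postop_day) rows")
    cols = ["patient_id", "postop_day"] + MOBILITY_VARS
    rows[cols].to_csv(path, index=False)


def read_daily_summaries(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = set(["patient_id", "postop_day"] + MOBILITY_VARS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing daily-summary columns {sorted(missing)}")
    df["postop_day"] = df["postop_day"].astype(int)
    return df
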