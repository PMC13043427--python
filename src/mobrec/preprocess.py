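"""Cleaning ladder for the daily-summary table.

Order of operations: censor the follow-up at 70 post-operative days, build
the complete patient x day grid (absent days become missing rows), exclude
any per-patient variable with more than 50% missing values, multiply impute
the remaining holes with chained random-forest models (m=5 datasets, up to
50 sweeps, fixed seed), consolidate by cell-wise pooling, remove gross
univariate outliers (Tukey fences, k=3 — an automated, testable surrogate
for the study's graphical inspection), and add log(x+1) columns for the
right-skewed variables.

Observed cells are never modified; every imputed/pooled/removed cell is
tracked in the dataset's provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .io_config import MOBILITY_VARS, RunConfig

log = logging.getLogger("mobrec")

INTEGER_VARS = {"sig_loc_count", "steps"}


@dataclass
class AnalyticDataset:
    """Pooled, imputed, outlier-filtered analytic table plus provenance."""
    data: pd.DataFrame
    imputed_mask: pd.DataFrame
    outlier_mask: pd.DataFrame
    excluded: list = field(default_factory=list)  # (patient_id, variable)
    log_variables: tuple = ()

    def analysis_values(self, var: str) -> pd.Series:
        """Values of one variable with outlier and patient-excluded cells set
        missing-for-analysis."""
        v = self.data[var].copy()
        v[self.outlier_mask[var].to_numpy()] = np.nan
        for pid, evar in self.excluded:
            if evar == var:
                v[self.data["patient_id"] == pid] = np.nan
        return v


def censor_followup(table: pd.DataFrame, censor_day: int = 70) -> pd.DataFrame:
    """Drop rows beyond the post-operative window (day `censor_day` kept)."""
    out = table[table["postop_day"] <= censor_day].reset_index(drop=True)
    n = len(table) - len(out)
    if n:
        log.info("censored %d rows beyond day %d", n, censor_day)
    return out


def complete_grid(table: pd.DataFrame, follow_up_days: int = 70,
                  patients: list | None = None) -> pd.DataFrame:
    """Reindex to the full patient x postop-day grid; absent days become
    all-missing rows so that missingness is explicit before imputation."""
    pids = patients if patients is not None else sorted(table["patient_id"].unique())
    idx = pd.MultiIndex.from_product([pids, range(1, follow_up_days + 1)],
                                     names=["patient_id", "postop_day"])
    out = (table.set_index(["patient_id", "postop_day"])
           .reindex(idx).reset_index())
    return out


def exclude_sparse_variables(table: pd.DataFrame, threshold: float = 0.5):
    """Per patient x variable: if the missing fraction is strictly greater
    than the threshold, mark that variable excluded for that patient (its
    values are removed from analysis and never imputed)."""
    table = table.copy()
    exclusions = []
    for pid, grp in table.groupby("patient_id"):
        for var in MOBILITY_VARS:
            frac = grp[var].isna().mean()
            if frac > threshold:
                table.loc[grp.index, var] = np.nan
                exclusions.append({"patient_id": pid, "variable": var,
                                   "missing_fraction": float(frac)})
    if exclusions:
        log.info("excluded %d patient-variables (>50%% missing)", len(exclusions))
    return table, exclusions


def _design_matrix(table: pd.DataFrame, approaches: dict | None) -> np.ndarray:
    day = table["postop_day"].to_numpy(dtype=float)[:, None]
    if approaches:
        app = table["patient_id"].map(
            lambda p: 1.0 if approaches.get(p) == "anterior" else 0.0
        ).to_numpy()[:, None]
    else:
        app = np.zeros((len(table), 1))
    pids = pd.get_dummies(table["patient_id"], dtype=float).to_numpy()
    return np.hstack([day, app, pids])


def impute_chained(table: pd.DataFrame, m: int = 5, iterations: int = 50,
                   seed: int = 0, approaches: dict | None = None,
                   n_estimators: int = 30) -> list[pd.DataFrame]:
    """Multiple imputation by chained equations with random-forest
    conditional models.

    Each mobility variable is iteratively regressed (random forest) on the
    other mobility variables plus post-operative day, surgical approach and
    patient indicators; `iterations` caps the number of chained sweeps
    (sweeps stop early once the largest standardized change of any imputed
    cell falls below 1e-3).  Returns m completed copies (per-imputation
    forest seeds); observed cells are untouched; deterministic under a
    fixed seed.
    """
    vars_ = MOBILITY_VARS
    X_mob = table[vars_].to_numpy(dtype=float)
    miss = np.isnan(X_mob)
    for j, var in enumerate(vars_):
        if miss[:, j].all():
            raise ValueError(f"variable {var!r} has no observed values; cannot impute")
    if not miss.any():
        return [table.copy() for _ in range(m)]
    X_extra = _design_matrix(table, approaches)
    col_sd = np.nanstd(X_mob, axis=0)
    days = table["postop_day"].to_numpy(dtype=float)
    rows_missing = np.flatnonzero(miss.any(axis=1))
    completed = []
    for k in range(m):
        rs = seed + 1000 * k
        rng = np.random.default_rng(rs)
        cur = X_mob.copy()
        # donor initialization: each missing row starts from a complete
        # observed row of a nearby post-operative day.  Means or trends as
        # starting values sit off the joint data manifold (e.g. an "average"
        # entropy belongs to no real day) and the strongly coupled
        # count/entropy pair then collapses onto a single branch; day-window
        # donors keep starting rows jointly coherent and day-appropriate
        for i in rows_missing:
            need = miss[i]
            for radius in (7.0, 21.0, np.inf):
                cand = np.flatnonzero((~miss[:, need].any(axis=1))
                                      & (np.abs(days - days[i]) <= radius))
                if cand.size:
                    donor = int(rng.choice(cand))
                    cur[i, need] = X_mob[donor, need]
                    break
            else:
                for j in np.flatnonzero(need):
                    cur[i, j] = np.nanmean(X_mob[:, j])
        for sweep in range(iterations):
            max_delta = 0.0
            for j, var in enumerate(vars_):
                mj = miss[:, j]
                if not mj.any():
                    continue
                feat = np.hstack([np.delete(cur, j, axis=1), X_extra])
                est = RandomForestRegressor(n_estimators=n_estimators, n_jobs=1,
                                            random_state=rs + j)
                est.fit(feat[~mj], X_mob[~mj, j])
                pred = est.predict(feat[mj])
                if var in INTEGER_VARS:
                    # keep integer columns on the data manifold during the
                    # chain (continuous "1.7 locations" would mislead the
                    # models of the coupled variables); stochastic rounding
                    # is mean-preserving
                    frac = pred - np.floor(pred)
                    pred = np.floor(pred) + (rng.random(len(pred)) < frac)
                if col_sd[j] > 0:
                    max_delta = max(max_delta,
                                    float(np.max(np.abs(pred - cur[mj, j]))) / col_sd[j])
                cur[mj, j] = pred
            if max_delta < 1e-3:
                break
        out = table.copy()
        round_rng = np.random.default_rng(rs + 17)
        for j, var in enumerate(vars_):
            col = cur[:, j]
            if var in INTEGER_VARS:
                # stochastic rounding: deterministic rounding of conditional
                # means is biased toward the modal integer
                frac = col - np.floor(col)
                col = np.floor(col) + (round_rng.random(len(col)) < frac)
            if var == "home_hours":
                col = np.clip(col, 0.0, 24.0)
            col = np.maximum(col, 0.0)
            out[var] = np.where(miss[:, j], col, X_mob[:, j])
        completed.append(out)
    return completed


def pool_imputations(tables: list[pd.DataFrame],
                     missing_mask: pd.DataFrame | None = None) -> AnalyticDataset:
    """Consolidate m completed tables into one analytic dataset: cell-wise
    mean for continuous variables, rounded mean for integer variables.
    ``missing_mask`` (pre-imputation missingness) becomes the provenance of
    pooled cells."""
    if not tables:
        raise ValueError("no imputations to pool")
    shape = tables[0].shape
    for t in tables[1:]:
        if t.shape != shape:
            raise ValueError("imputed tables have mismatched shapes")
    base = tables[0].copy()
    arr = np.stack([t[MOBILITY_VARS].to_numpy(dtype=float) for t in tables])
    pooled = arr.mean(axis=0)
    imputed_mask = pd.DataFrame(False, index=base.index, columns=MOBILITY_VARS)
    if missing_mask is not None:
        imputed_mask.loc[:, :] = missing_mask[MOBILITY_VARS].to_numpy()
    elif len(tables) > 1:
        spread = arr.max(axis=0) - arr.min(axis=0)
        imputed_mask.loc[:, :] = spread > 1e-12
    for j, var in enumerate(MOBILITY_VARS):
        col = pooled[:, j]
        if var in INTEGER_VARS:
            col = np.round(col)
        base[var] = col
    outlier_mask = pd.DataFrame(False, index=base.index, columns=MOBILITY_VARS)
    return AnalyticDataset(data=base, imputed_mask=imputed_mask,
                           outlier_mask=outlier_mask)


def remove_outliers(dataset: AnalyticDataset, k: float = 3.0):
    """Tukey-fence outlier removal: per variable, cells outside
    [Q1 - k*IQR, Q3 + k*IQR] are marked removed (row retained, cell missing
    for analysis).  Columns with IQR = 0 are left untouched."""
    report = []
    for var in MOBILITY_VARS:
        x = dataset.data[var].to_numpy(dtype=float)
        obs = x[~np.isnan(x)]
        if obs.size == 0:
            continue
        q1, q3 = np.percentile(obs, [25, 75])
        iqr = q3 - q1
        if iqr <= 0:
            continue
        lo, hi = q1 - k * iqr, q3 + k * iqr
        mask = (~np.isnan(x)) & ((x < lo) | (x > hi))
        dataset.outlier_mask[var] = dataset.outlier_mask[var].to_numpy() | mask
        for i in np.flatnonzero(mask):
            report.append({"row": int(i), "variable": var, "value": float(x[i]),
                           "lower": float(lo), "upper": float(hi)})
    if report:
        log.info("flagged %d outlier cells", len(report))
    return dataset, report


def log_transform(dataset: AnalyticDataset,
                  variables=("distance_km", "steps", "sig_loc_entropy")) -> AnalyticDataset:
    """Add ln(x+1) columns (suffix `_log`) for right-skewed variables;
    originals are retained for raw-scale summaries."""
    for var in variables:
        x = dataset.data[var].to_numpy(dtype=float)
        if np.nanmin(x) < 0:
            raise ValueError(f"{var} has negative values; log transform undefined")
        dataset.data[f"{var}_log"] = np.log1p(x)
    dataset.log_variables = tuple(variables)
    return dataset


def run_ladder(table: pd.DataFrame, config: RunConfig | None = None,
               approaches: dict | None = None,
               patients: list | None = None) -> tuple[AnalyticDataset, dict]:
    """The full cleaning ladder; returns the analytic dataset and a report."""
    cfg = config or RunConfig()
    censored = censor_followup(table, cfg.censor_day)
    grid = complete_grid(censored, cfg.censor_day, patients)
    grid, exclusions = exclude_sparse_variables(grid, cfg.missing_fraction_threshold)
    miss_mask = grid[MOBILITY_VARS].isna()
    completed = impute_chained(grid, m=cfg.mice_m, iterations=cfg.mice_iterations,
                               seed=cfg.mice_seed, approaches=approaches)
    dataset = pool_imputations(completed, missing_mask=miss_mask)
    dataset.excluded = [(e["patient_id"], e["variable"]) for e in exclusions]
    # excluded patient-variables are removed from analysis, not imputed
    for pid, var in dataset.excluded:
        dataset.data.loc[dataset.data["patient_id"] == pid, var] = np.nan
    dataset, outliers = remove_outliers(dataset, cfg.outlier_k)
    dataset = log_transform(dataset, cfg.log_variables)
    report = {
        "n_rows": int(len(dataset.data)),
        "censored_to_day": cfg.censor_day,
        "exclusions": exclusions,
        "n_imputed_cells": int(dataset.imputed_mask.to_numpy().sum()),
        "n_outlier_cells": int(dataset.outlier_mask.to_numpy().sum()),
        "log_variables": list(cfg.log_variables),
    }
    return dataset, report
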