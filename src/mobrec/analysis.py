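"""Statistical analyses on the analytic dataset.

Three objectives: (1) week-1 vs week-5 comparison of the five mobility
variables (raw-scale means with t-based 95% CIs, two-sided Wilcoxon rank-sum
— rank tests are invariant to the log transform, so raw values are used);
(2) per-variable GLM recovery trajectories with a Postop Day x Surgery
Approach interaction (Gamma log-link for distance/home/entropy, Poisson
log-link for count/steps, Gaussian available as the unifying baseline);
(3) Pearson correlations between mobility variables and PROMs with
Benjamini-Hochberg FDR control, plus per-pair Gaussian-GLM relationship
curves with pointwise 95% Wald bands.

Observations are treated as independent across days within patients, the
same working assumption the pooled tests make; no mixed-effects correction
is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_config import MOBILITY_VARS
from .preprocess import AnalyticDataset

log = logging.getLogger("mobrec")

WEEK_DAYS = {1: range(1, 8), 5: range(29, 36)}
DEFAULT_FAMILIES = {
    "distance_km": "gamma",
    "home_hours": "gamma",
    "sig_loc_entropy": "gamma",
    "sig_loc_count": "poisson",
    "steps": "poisson",
}
PROM_ORDER = ["VAS", "mJOA", "ODI", "NDI"]


def _week_days(week: int) -> np.ndarray:
    return np.arange(7 * (week - 1) + 1, 7 * week + 1)


def _mean_ci(x: np.ndarray, level: float = 0.95):
    x = x[~np.isnan(x)]
    n = len(x)
    m = float(np.mean(x))
    if n < 2:
        return m, np.nan, np.nan, n
    se = float(np.std(x, ddof=1)) / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + level / 2.0, n - 1)
    return m, m - tcrit * se, m + tcrit * se, n


def week_comparison(dataset: AnalyticDataset, week_a: int = 1,
                    week_b: int = 5) -> pd.DataFrame:
    """Raw-scale means with t-based 95% CIs for two post-operative weeks and
    the two-sided Wilcoxon rank-sum p-value, per mobility variable.

    Weeks are post-operative days 7(w-1)+1..7w (days 1-7 and 29-35 for the
    default pair)."""
    rows = []
    df = dataset.data
    for var in MOBILITY_VARS:
        v = dataset.analysis_values(var).to_numpy(dtype=float)
        xa = v[df["postop_day"].isin(_week_days(week_a)).to_numpy()]
        xb = v[df["postop_day"].isin(_week_days(week_b)).to_numpy()]
        xa, xb = xa[~np.isnan(xa)], xb[~np.isnan(xb)]
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"week comparison for {var!r}: a week is empty "
                             f"(week {week_a}: n={len(xa)}, week {week_b}: n={len(xb)})")
        ma, loa, hia, na = _mean_ci(xa)
        mb, lob, hib, nb = _mean_ci(xb)
        method = "exact" if max(len(xa), len(xb)) <= 25 else "asymptotic"
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        rows.append({"variable": var,
                     "week_a": week_a, "mean_a": ma, "ci_low_a": loa,
                     "ci_high_a": hia, "n_a": na,
                     "week_b": week_b, "mean_b": mb, "ci_low_b": lob,
                     "ci_high_b": hib, "n_b": nb,
                     "wilcoxon_p": float(res.pvalue)})
    return pd.DataFrame(rows)


@dataclass
class GlmFit:
    """One fitted recovery trajectory."""
    variable: str
    family: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    converged: bool
    n_obs: int
    zero_offset_used: bool = False
    result: object = field(default=None, repr=False)

    def predict(self, postop_day, approach: str) -> np.ndarray:
        """Per-arm fitted mean trajectory."""
        d = np.asarray(postop_day, dtype=float)
        if self.result is None:  # degenerate constant fit
            icpt = self.params["intercept"]
            mu = np.exp(icpt) if self.family in ("gamma", "poisson") else icpt
            return np.full_like(d, mu)
        a = 1.0 if approach == "anterior" else 0.0
        X = np.column_stack([np.ones_like(d), d, np.full_like(d, a), d * a])
        return self.result.predict(X)


def _family(name: str):
    if name == "gaussian":
        return sm.families.Gaussian()
    if name == "gamma":
        return sm.families.Gamma(link=sm.families.links.Log())
    if name == "poisson":
        return sm.families.Poisson()
    raise ValueError(f"unknown GLM family {name!r}")


def fit_recovery_glm(dataset: AnalyticDataset, variable: str,
                     family: str | None = None,
                     zero_offset: float = 0.01) -> GlmFit:
    """Fit mean(variable) = g^-1(b0 + b1*postop_day + b2*approach +
    b3*postop_day*approach).

    ``approach`` codes anterior = 1, posterior = 0.  The Gamma family
    requires positive responses; admissible zeros are shifted by
    ``zero_offset`` (logged)."""
    family = family or DEFAULT_FAMILIES.get(variable, "gaussian")
    df = dataset.data
    y = dataset.analysis_values(variable).to_numpy(dtype=float)
    day = df["postop_day"].to_numpy(dtype=float)
    anterior = (df["approach"] == "anterior").to_numpy(dtype=float)
    ok = ~np.isnan(y)
    y, day, anterior = y[ok], day[ok], anterior[ok]
    zero_used = False
    if family == "gamma":
        if np.any(y < 0):
            raise ValueError(f"{variable}: negative values under Gamma family")
        if np.any(y == 0):
            if zero_offset <= 0:
                raise ValueError(f"{variable}: zeros under Gamma family and no offset")
            log.info("%s: shifting %d zero responses by %g for Gamma fit",
                     variable, int((y == 0).sum()), zero_offset)
            y = y + zero_offset
            zero_used = True
    X = np.column_stack([np.ones_like(day), day, anterior, day * anterior])
    names = ["intercept", "postop_day", "approach", "postop_day:approach"]
    if np.ptp(y) == 0.0:
        # constant response: flat fit, zero slopes (statsmodels cannot
        # evaluate the deviance at zero dispersion)
        icpt = float(np.log(y[0])) if family in ("gamma", "poisson") else float(y[0])
        zeros = pd.Series(np.zeros(4), index=names)
        params = zeros.copy()
        params["intercept"] = icpt
        ci = pd.DataFrame({"low": params, "high": params}, index=names)
        return GlmFit(variable=variable, family=family, params=params,
                      bse=zeros.copy(), pvalues=zeros + np.nan, conf_int=ci,
                      converged=True, n_obs=len(y), zero_offset_used=zero_used,
                      result=None)
    model = sm.GLM(y, X, family=_family(family))
    res = model.fit()
    if not res.converged:
        raise RuntimeError(
            f"GLM for {variable} ({family}) did not converge: "
            f"{getattr(res, 'fit_history', None)}")
    ci = pd.DataFrame(res.conf_int(), index=names, columns=["low", "high"])
    return GlmFit(variable=variable, family=family,
                  params=pd.Series(res.params, index=names),
                  bse=pd.Series(res.bse, index=names),
                  pvalues=pd.Series(res.pvalues, index=names),
                  conf_int=ci, converged=bool(res.converged), n_obs=len(y),
                  zero_offset_used=zero_used, result=res)


def fit_all_glms(dataset: AnalyticDataset, zero_offset: float = 0.01) -> dict:
    return {var: fit_recovery_glm(dataset, var, zero_offset=zero_offset)
            for var in MOBILITY_VARS}


# ---------------------------------------------------------------------------
# PROM correlation
# ---------------------------------------------------------------------------

def _prom_pairs(dataset: AnalyticDataset, proms: pd.DataFrame,
                surgery_dates: dict) -> pd.DataFrame:
    """Resolve PROM responses to mobility values.

    Daily VAS pairs with the same patient-day; weekly instruments pair with
    the patient's mean mobility over the 7 days ending on the response date.
    All available non-missing observations are used."""
    df = dataset.data
    vals = {var: dataset.analysis_values(var) for var in MOBILITY_VARS}
    mob = df[["patient_id", "postop_day"]].copy()
    for var in MOBILITY_VARS:
        mob[var] = vals[var]
    rows = []
    for _, r in proms.iterrows():
        pid = r["patient_id"]
        if pid not in surgery_dates:
            continue
        day = (pd.Timestamp(r["date"]) - pd.Timestamp(surgery_dates[pid])).days
        sub = mob[mob["patient_id"] == pid]
        if r["instrument"] == "VAS":
            sel = sub[sub["postop_day"] == day]
        else:
            sel = sub[(sub["postop_day"] >= day - 6) & (sub["postop_day"] <= day)]
        if len(sel) == 0:
            continue
        row = {"patient_id": pid, "instrument": r["instrument"],
               "score": float(r["score"]), "postop_day": day}
        for var in MOBILITY_VARS:
            row[var] = float(sel[var].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def correlate_proms(dataset: AnalyticDataset, proms: pd.DataFrame,
                    surgery_dates: dict, fdr_method: str = "fdr_bh") -> pd.DataFrame:
    """Pearson correlations between the 5 mobility variables and 4 PROMs with
    Benjamini-Hochberg adjustment across the 20 tests.

    Pairs with fewer than 3 complete observations are marked not estimable
    (NaN r/p) and skipped by the adjustment."""
    pairs = _prom_pairs(dataset, proms, surgery_dates)
    rows = []
    for inst in PROM_ORDER:
        sub = pairs[pairs["instrument"] == inst]
        for var in MOBILITY_VARS:
            if len(sub) == 0:
                rows.append({"instrument": inst, "variable": var, "r": np.nan,
                             "p": np.nan, "n": 0})
                continue
            x = sub[var].to_numpy(dtype=float)
            y = sub["score"].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            n = int(ok.sum())
            if n < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                rows.append({"instrument": inst, "variable": var, "r": np.nan,
                             "p": np.nan, "n": n})
                continue
            r, p = stats.pearsonr(x[ok], y[ok])
            rows.append({"instrument": inst, "variable": var, "r": float(r),
                         "p": float(p), "n": n})
    out = pd.DataFrame(rows)
    mask = out["p"].notna()
    out["p_fdr"] = np.nan
    if mask.any():
        out.loc[mask, "p_fdr"] = multipletests(out.loc[mask, "p"],
                                               method=fdr_method)[1]
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def relationship_curves(dataset: AnalyticDataset, proms: pd.DataFrame,
                        surgery_dates: dict, n_grid: int = 50) -> dict:
    """Per (mobility, PROM) pair: Gaussian GLM of score on the mobility value
    with a pointwise 95% Wald band, on an x grid spanning the observed range.

    Degenerate pairs (zero x variance or < 3 points) are omitted."""
    pairs = _prom_pairs(dataset, proms, surgery_dates)
    curves = {}
    for inst in PROM_ORDER:
        sub = pairs[pairs["instrument"] == inst]
        for var in MOBILITY_VARS:
            if len(sub) < 3:
                continue
            x = sub[var].to_numpy(dtype=float)
            y = sub["score"].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            x, y = x[ok], y[ok]
            if len(x) < 3 or np.std(x) == 0:
                continue
            gx0 = np.linspace(x.min(), x.max(), n_grid)
            if np.ptp(y) == 0.0:
                # constant score: flat line, zero-width band
                curves[(var, inst)] = pd.DataFrame({
                    "x": gx0, "fit": y[0], "lower": y[0], "upper": y[0]})
                continue
            X = sm.add_constant(x)
            res = sm.GLM(y, X, family=sm.families.Gaussian()).fit()
            gx = np.linspace(x.min(), x.max(), n_grid)
            GX = sm.add_constant(gx)
            pred = res.get_prediction(GX)
            ci = pred.conf_int()
            curves[(var, inst)] = pd.DataFrame({
                "x": gx, "fit": pred.predicted_mean,
                "lower": ci[:, 0], "upper": ci[:, 1]})
    return curves
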