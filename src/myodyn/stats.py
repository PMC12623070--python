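"""Cohort-level biomarker statistics.

For each muscle x variable the two groups (healthy controls, patients)
are summarized as median and interquartile range, and their
discriminative power quantified by standardized logistic regression: the
binarized group (patient = 1) is regressed on the z-scored variable, and
exp(slope) is the odds ratio per one standard deviation.  95% confidence
intervals come from the profile likelihood (with a Wald fallback, always
flagged): under quasi-separation a profile endpoint can be unbounded and
is reported as undefined (NaN), which is how such tables print "NA".
Associations between dynamic (strain, rates) and structural (fat
fraction, water T2) biomarkers are measured by Spearman correlation,
pooled over all subjects and muscles.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import chi2, spearmanr

__all__ = [
    "LogisticResult",
    "median_iqr",
    "standardized_logistic_or",
    "spearman_rho",
    "reproduce_results",
    "load_subject_table",
    "save_results",
    "MUSCLES",
    "VARIABLES",
]

MUSCLES = ("soleus", "medial_gastrocnemius", "lateral_gastrocnemius")
VARIABLES = ("strain", "buildup_rate", "release_rate", "fat_fraction",
             "water_t2")
REQUIRED_COLUMNS = ("subject_id", "group", "muscle", *VARIABLES, "mvf")

_CHI2_95 = float(chi2.ppf(0.95, df=1))  # 3.841...


@dataclass
class LogisticResult:
    """Standardized logistic regression outcome for one variable."""

    odds_ratio: float
    ci_low: float        # NaN when the profile endpoint is unbounded
    ci_high: float
    n: int
    converged: bool
    separation: bool
    slope: float
    wald_fallback: bool = False


def median_iqr(values: Sequence[float] | np.ndarray
               ) -> tuple[float, float, float]:
    """Median and quartiles (linear-interpolation convention).

    Missing values are dropped (count logged via warning when any);
    an all-missing input is an error.
    """
    x = np.asarray(values, dtype=float)
    n_missing = int(np.isnan(x).sum())
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("all values missing")
    if n_missing:
        warnings.warn(f"median_iqr: dropped {n_missing} missing values")
    med, q1, q3 = np.percentile(x, [50, 25, 75])
    return float(med), float(q1), float(q3)


def _loglik(beta0: float, beta1: float, z: np.ndarray, y: np.ndarray
            ) -> float:
    eta = beta0 + beta1 * z
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _profile_loglik(beta1: float, z: np.ndarray, y: np.ndarray,
                    b0_start: float = 0.0) -> float:
    """Log-likelihood profiled over the intercept (1-D Newton)."""
    b0 = b0_start
    for _ in range(100):
        eta = b0 + beta1 * z
        p = expit(eta)
        grad = float(np.sum(y - p))
        hess = -float(np.sum(p * (1.0 - p)))
        if hess > -1e-12:
            break
        step = grad / hess
        b0 -= step
        if abs(step) < 1e-12:
            break
    return _loglik(b0, beta1, z, y)


def _complete_separation(z: np.ndarray, y: np.ndarray) -> bool:
    z0, z1 = z[y == 0], z[y == 1]
    return bool(z0.max() < z1.min() or z1.max() < z0.min())


def standardized_logistic_or(
    x: Sequence[float] | np.ndarray,
    group: Sequence[int] | np.ndarray,
    slope_bound: float = 40.0,
) -> LogisticResult:
    """Odds ratio per standard deviation of ``x`` for group membership.

    x is z-scored over all subjects pooled (mean-detrended, divided by the
    n-1 sample standard deviation); group (0/1) is regressed on it by
    maximum likelihood with an intercept.  The 95% CI is the profile
    likelihood interval; an endpoint that stays inside the 95% deviance
    band out to ``slope_bound`` (quasi-separation) is undefined (NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(group, dtype=float)
    keep = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[keep], y[keep]
    n = x.size
    if len(np.unique(y)) < 2:
        raise ValueError("both groups must be represented")
    if min((y == 0).sum(), (y == 1).sum()) < 3:
        raise ValueError("need at least 3 subjects per group")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("variable is constant")
    z = (x - x.mean()) / sd

    separation = _complete_separation(z, y)
    design = sm.add_constant(z)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, design)
        try:
            fit = model.fit(disp=0, method="newton", maxiter=100)
        except Exception:
            fit = model.fit(disp=0, method="lbfgs", maxiter=500)
    slope = float(fit.params[1])
    converged = bool(getattr(fit, "mle_retvals", {}).get("converged", True))
    if separation:
        slope = float(np.clip(slope, -slope_bound, slope_bound))

    llmax = _profile_loglik(slope, z, y, b0_start=float(fit.params[0]))

    def dev(b1: float) -> float:
        return 2.0 * (llmax - _profile_loglik(b1, z, y)) - _CHI2_95

    ci = [np.nan, np.nan]
    wald_fallback = False
    for side, sgn in (("low", -1.0), ("high", 1.0)):
        try:
            step = 0.5
            b = slope + sgn * step
            while dev(b) < 0 and abs(b - slope) < slope_bound:
                step *= 2.0
                b = slope + sgn * step
            if dev(b) < 0:
                endpoint = np.nan  # unbounded: print as NA
            else:
                endpoint = brentq(dev, min(slope, b), max(slope, b),
                                  xtol=1e-8)
        except Exception:
            se = float(fit.bse[1])
            endpoint = slope + sgn * 1.96 * se
            wald_fallback = True
            warnings.warn("profile CI failed; Wald fallback used")
        ci[0 if side == "low" else 1] = endpoint

    return LogisticResult(
        odds_ratio=float(np.exp(slope)),
        ci_low=float(np.exp(ci[0])) if np.isfinite(ci[0]) else np.nan,
        ci_high=float(np.exp(ci[1])) if np.isfinite(ci[1]) else np.nan,
        n=n,
        converged=converged,
        separation=separation,
        slope=slope,
        wald_fallback=wald_fallback,
    )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (ties get average ranks).

    Pairs with a missing member are dropped; a constant input is
    undefined and returned as NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 paired non-missing values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined")
        return float("nan")
    rho, _ = spearmanr(x, y)
    return float(rho)


def load_subject_table(path: str | Path,
                       column_map: Mapping[str, str] | None = None
                       ) -> pd.DataFrame:
    """Read a per-subject, per-muscle CSV, optionally renaming columns.

    ``column_map`` maps source column names to the canonical names
    (subject_id, group, muscle, strain, buildup_rate, release_rate,
    fat_fraction, water_t2, mvf), so externally deposited tables with a
    different dialect can be ingested.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subject table is missing columns: {missing}")
    return df


def reproduce_results(table: pd.DataFrame) -> dict:
    """Full statistics bundle from a subject table.

    Per muscle x variable: group medians/IQRs and the standardized
    logistic odds ratio with profile CI; MVF is summarized once per
    subject.  Spearman correlations of the dynamic variables against fat
    fraction and water T2 are pooled over all rows.  Returns a dict with
    ``summary`` (long-format rows), ``odds_ratios`` and ``correlations``
    DataFrames plus a machine-readable ``json`` payload.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"subject table is missing columns: {missing}")

    summary_rows = []
    or_rows = []

    def add_variable(scope: str, values: pd.Series, groups: pd.Series,
                     variable: str) -> None:
        vals = values.to_numpy(dtype=float)
        grp = groups.to_numpy(dtype=int)
        med_hc = median_iqr(vals[grp == 0])
        med_pat = median_iqr(vals[grp == 1])
        res = standardized_logistic_or(vals, grp)
        summary_rows.append({
            "muscle": scope, "variable": variable,
            "hc_median": med_hc[0], "hc_q1": med_hc[1], "hc_q3": med_hc[2],
            "patient_median": med_pat[0], "patient_q1": med_pat[1],
            "patient_q3": med_pat[2],
        })
        or_rows.append({
            "muscle": scope, "variable": variable, **asdict(res),
        })

    per_subject = table.drop_duplicates("subject_id")
    add_variable("all", per_subject["mvf"], per_subject["group"], "mvf")
    for muscle in MUSCLES:
        sub = table[table["muscle"] == muscle]
        if sub.empty:
            continue
        for var in VARIABLES:
            add_variable(muscle, sub[var], sub["group"], var)

    corr_rows = []
    for dyn in ("strain", "buildup_rate", "release_rate"):
        row = {"variable": dyn}
        for quant in ("fat_fraction", "water_t2"):
            row[quant] = spearman_rho(table[dyn], table[quant])
        corr_rows.append(row)

    summary = pd.DataFrame(summary_rows)
    odds = pd.DataFrame(or_rows)
    corr = pd.DataFrame(corr_rows).set_index("variable")
    payload = {
        "summary": summary.to_dict(orient="records"),
        "odds_ratios": odds.to_dict(orient="records"),
        "correlations": corr.reset_index().to_dict(orient="records"),
        "n_subjects": int(table["subject_id"].nunique()),
        "n_rows": int(len(table)),
    }
    return {"summary": summary, "odds_ratios": odds, "correlations": corr,
            "json": payload}


def save_results(results: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write results.json, table1.csv and correlations.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "json": out / "results.json",
        "table1": out / "table1.csv",
        "correlations": out / "correlations.csv",
    }
    paths["json"].write_text(json.dumps(results["json"], indent=2,
                                        default=float))
    merged = results["summary"].merge(
        results["odds_ratios"][["muscle", "variable", "odds_ratio",
                                "ci_low", "ci_high", "separation"]],
        on=["muscle", "variable"],
    )
    merged.to_csv(paths["table1"], index=False)
    results["correlations"].to_csv(paths["correlations"])
    return paths
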