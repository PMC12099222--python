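"""Multi-session aggregation and the study-level statistical models.

Session records (one row per QC session) carry site id, date, software tag,
PSNR (dB) and its transform modPSNR = 10^(PSNR/10), WM/GM contrast,
thermometer temperature with its capped flag, Larmor center frequency, and
per-radius-group distortion means.  On top of them:

* the Larmor-frequency/temperature model: one shared temperature slope with
  a separate intercept per site (magnets differ in baseline field, their
  thermal coefficient does not).  Estimated as a fixed per-site-intercept
  least-squares model (dummy-variable estimator) — for a shared slope with
  site-specific intercepts this matches the mixed-model slope estimand
  while staying closed-form and deterministic.  Sessions whose temperature
  reading saturated at the thermometer maximum are excluded, since their
  true temperature is unknown.
* one-way fixed-effects ANOVA across sites for any metric.
* longitudinal per-site summaries: ordered time series, empirical 95%
  coverage interval widths (2.5-97.5 percentiles), and software-update
  change-points from software-tag transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

SESSION_COLUMNS = [
    "site", "date", "software_tag", "psnr_db", "mod_psnr", "con",
    "temperature_c", "capped", "larmor_mhz",
    "dist_r0_mm", "dist_r50_mm", "dist_r70_mm",
]


@dataclass(frozen=True)
class SiteInterceptModel:
    shared_slope: float  # MHz / deg C
    slope_stderr: float
    intercepts: dict[str, float]  # per-site, MHz at 0 deg C
    n_sessions: int
    pooled_slope: float  # single OLS line over all sites, for contrast
    pooled_slope_pvalue: float


def transform_mod_psnr(psnr_db) -> float | np.ndarray:
    """PSNR (dB) -> modPSNR = 10^(PSNR/10), a near-normal working variable."""
    psnr_db = np.asarray(psnr_db, dtype=float)
    if not np.all(np.isfinite(psnr_db)):
        raise ValueError("PSNR must be finite")
    out = 10.0 ** (psnr_db / 10.0)
    return float(out) if out.ndim == 0 else out


def fit_site_intercept_model(records: pd.DataFrame) -> SiteInterceptModel:
    """Shared Larmor-frequency temperature slope with per-site intercepts.

    Capped-temperature sessions are dropped before fitting.  With a single
    site the model reduces to simple linear regression.  The pooled
    single-line OLS fit over all sites is returned alongside for contrast
    (between-site baseline differences mask the within-site slope there).
    """
    import statsmodels.formula.api as smf

    df = records.copy()
    if "capped" in df:
        df = df[~df["capped"].astype(bool)]
    df = df.dropna(subset=["larmor_mhz", "temperature_c", "site"])
    sites = df["site"].unique()
    if len(df) < 3 or len(sites) < 1:
        raise ValueError("insufficient non-capped sessions for the temperature model")
    counts = df.groupby("site").size()
    if (counts < 2).any():
        raise ValueError("every included site needs >= 2 non-capped sessions")

    fit = smf.ols("larmor_mhz ~ 0 + C(site) + temperature_c", data=df).fit()
    slope = float(fit.params["temperature_c"])
    stderr = float(fit.bse["temperature_c"])
    intercepts = {}
    for s in sites:
        key = f"C(site)[{s}]"
        intercepts[str(s)] = float(fit.params[key])

    pooled = smf.ols("larmor_mhz ~ temperature_c", data=df).fit()
    return SiteInterceptModel(
        shared_slope=slope, slope_stderr=stderr, intercepts=intercepts,
        n_sessions=int(len(df)),
        pooled_slope=float(pooled.params["temperature_c"]),
        pooled_slope_pvalue=float(pooled.pvalues["temperature_c"]),
    )


def anova_across_sites(values, site_labels) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of a metric across sites: (F, p)."""
    values = np.asarray(values, dtype=float)
    site_labels = np.asarray(site_labels)
    groups = [values[site_labels == s] for s in pd.unique(site_labels)]
    if len(groups) < 2:
        raise ValueError("need >= 2 sites")
    if any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 sessions per site")
    if np.ptp(values) == 0:  # no variance anywhere: zero between-group effect
        return 0.0, 1.0
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def longitudinal_summary(records: pd.DataFrame, site: str,
                         metrics: tuple[str, ...] = ("psnr_db", "con", "dist_r50_mm", "temperature_c")) -> dict:
    """Per-metric time series and 95% coverage interval widths for one site.

    The coverage interval is the empirical 2.5-97.5 percentile range.
    Software-update change-points are the first sessions bearing a new
    software tag.
    """
    df = records[records["site"] == site].copy()
    if len(df) < 3:
        raise ValueError(f"need >= 3 sessions for site {site!r}")
    df["date"] = pd.to_datetime(df["date"])
    df = df.sort_values("date").reset_index(drop=True)

    out: dict = {"site": site, "n_sessions": int(len(df)), "metrics": {}}
    for m in metrics:
        if m not in df or df[m].isna().all():
            continue
        vals = df[m].dropna().to_numpy(dtype=float)
        lo, hi = np.percentile(vals, [2.5, 97.5])
        out["metrics"][m] = {
            "series": [
                {"date": d.date().isoformat(), "value": float(v)}
                for d, v in zip(df["date"], df[m])
                if np.isfinite(v)
            ],
            "coverage_interval_width": float(hi - lo),
        }
    tags = df["software_tag"].astype(str)
    change_points = [
        df.loc[i, "date"].date().isoformat()
        for i in range(1, len(df))
        if tags.iloc[i] != tags.iloc[i - 1]
    ]
    out["software_change_points"] = change_points
    return out


def study_report(records: pd.DataFrame) -> dict:
    """Cross-site study summary: distributions, temperature model, ANOVA."""
    report: dict = {"n_sessions": int(len(records)), "sites": sorted(map(str, records["site"].unique()))}
    psnr = records["psnr_db"].dropna()
    if len(psnr):
        report["psnr_db"] = {"mean": float(psnr.mean()), "min": float(psnr.min()), "max": float(psnr.max())}
    try:
        model = fit_site_intercept_model(records)
        report["larmor_temperature_model"] = {
            "shared_slope_mhz_per_c": model.shared_slope,
            "slope_stderr": model.slope_stderr,
            "intercepts_mhz": model.intercepts,
            "n_sessions": model.n_sessions,
            "pooled_ols_slope": model.pooled_slope,
            "pooled_ols_pvalue": model.pooled_slope_pvalue,
        }
    except ValueError as exc:
        report["larmor_temperature_model"] = {"error": str(exc)}
    try:
        ok = records.dropna(subset=["mod_psnr"])
        f, p = anova_across_sites(ok["mod_psnr"], ok["site"])
        report["mod_psnr_anova"] = {"F": f, "p": p}
    except ValueError as exc:
        report["mod_psnr_anova"] = {"error": str(exc)}
    longitudinal = {}
    for site in records["site"].unique():
        try:
            longitudinal[str(site)] = longitudinal_summary(records, site)
        except ValueError:
            continue
    report["longitudinal"] = longitudinal
    return report
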