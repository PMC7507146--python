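"""Stoichiometric homeostasis (1/H) and discharge-ratio power laws.

The homeostasis coefficient H relates resource and consumer stoichiometry;
its reciprocal 1/H is estimated as the ordinary least-squares slope of
log10(particulate N:P) on log10(dissolved inorganic N:P).  1/H near 0 means
the particulate ratio is static (chemostatic) across the dissolved supply;
1/H near 1 means proportional, plastic tracking.  The slope is independent
of the log base; intercepts are reported in log10.

Discharge dependence is summarised per site by the power law N:P = a Q^b,
fitted as an OLS of log10(N:P) on log10(Q): b = 0 is chemostatic behaviour
of the ratio across flows.

Both estimators are plain OLS (no errors-in-variables correction even though
both ratios are noisy); constant-response inputs short-circuit to a slope of
exactly 0 so the degenerate limits are exact rather than floating-point
residue.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HomeostasisFit",
    "PowerLawFit",
    "InsufficientDataError",
    "fit_homeostasis",
    "fit_homeostasis_by_tp_bin",
    "per_site_homeostasis",
    "fit_power_law",
    "site_power_laws",
    "regress_b_on_landuse",
]


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class HomeostasisFit:
    slope_inv_h: float
    intercept_log_c: float
    p_value: float
    stderr: float
    n: int
    subset_label: str = ""


def _loglog_ols(logx: np.ndarray, logy: np.ndarray):
    """Slope, intercept, p, stderr with exact degenerate limits."""
    if np.ptp(logx) == 0.0:
        raise ValueError("degenerate predictor: zero variance in log x")
    if np.ptp(logy) == 0.0:
        return 0.0, float(logy[0]), 1.0, 0.0
    fit = stats.linregress(logx, logy)
    return float(fit.slope), float(fit.intercept), float(fit.pvalue), float(fit.stderr)


def fit_homeostasis(dissolved, particulate, label: str = "all") -> HomeostasisFit:
    """OLS of log10 particulate N:P on log10 dissolved N:P; slope = 1/H."""
    x = np.asarray(dissolved, dtype=float)
    y = np.asarray(particulate, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 ratio pairs, got {x.size}")
    logx, logy = np.log10(x), np.log10(y)
    try:
        slope, intercept, p, se = _loglog_ols(logx, logy)
    except ValueError:
        raise ValueError("degenerate dissolved N:P: zero variance") from None
    return HomeostasisFit(slope, intercept, p, se, int(x.size), label)


def fit_homeostasis_by_tp_bin(
    frame: pd.DataFrame,
    tp_low: float = 0.025,
    tp_high: float = 0.10,
    dissolved_col: str = "np_dissolved",
    particulate_col: str = "np_particulate",
) -> dict[str, HomeostasisFit | None]:
    """1/H in low-TP (TP < tp_low) and high-TP (TP > tp_high) subsets.

    TP (mg/L) is a proxy for suspended autotrophic biomass; strict
    inequalities, the middle band is excluded.  An empty bin is omitted with
    a warning.
    """
    fits: dict[str, HomeostasisFit | None] = {}
    for label, mask in (
        (f"tp_lt_{tp_low:g}", frame["TP"] < tp_low),
        (f"tp_gt_{tp_high:g}", frame["TP"] > tp_high),
    ):
        sub = frame[mask]
        try:
            fits[label] = fit_homeostasis(
                sub[dissolved_col], sub[particulate_col], label=label
            )
        except InsufficientDataError:
            warnings.warn(f"TP bin {label!r} has too few records; fit omitted")
            fits[label] = None
    return fits


def per_site_homeostasis(
    frame: pd.DataFrame,
    min_n: int = 100,
    dissolved_col: str = "np_dissolved",
    particulate_col: str = "np_particulate",
) -> tuple[pd.DataFrame, list[str]]:
    """Site-specific 1/H for sites with strictly more than min_n complete pairs.

    Returns a table with one row per eligible site (1/H, p-value, n, and
    medians with quartiles of DIN:DIP, PN:PP and TN:TP) plus the list of
    ineligible sites.
    """
    rows, ineligible = [], []
    for site, sub in frame.groupby("site_id", sort=True):
        x = sub[dissolved_col].to_numpy(float)
        y = sub[particulate_col].to_numpy(float)
        keep = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
        if keep.sum() <= min_n:
            ineligible.append(str(site))
            continue
        fit = fit_homeostasis(x[keep], y[keep], label=str(site))
        row = {"site_id": str(site), "n": fit.n, "inv_h": fit.slope_inv_h,
               "log_c": fit.intercept_log_c, "p_value": fit.p_value}
        for name, col in (("din_dip", dissolved_col), ("pn_pp", particulate_col),
                          ("tn_tp", "np_total")):
            if col in sub.columns:
                v = sub[col].to_numpy(float)
                v = v[np.isfinite(v)]
                if v.size:
                    q1, med, q3 = np.percentile(v, [25, 50, 75])
                    row.update({f"{name}_median": med, f"{name}_q1": q1, f"{name}_q3": q3})
        rows.append(row)
    return pd.DataFrame(rows), ineligible


@dataclass(frozen=True)
class PowerLawFit:
    site_id: str
    a_coeff: float  # N:P at unit discharge
    b_exp: float  # power-law exponent
    n: int
    ratio_kind: str  # total | dissolved | particulate
    p_value: float = np.nan
    stderr: float = np.nan


def fit_power_law(q, np_ratio, ratio_kind: str = "total", site_id: str = "",
                  min_n: int = 10) -> PowerLawFit:
    """Fit N:P = a Q^b by OLS of log10(N:P) on log10(Q).

    Requires strictly more than ``min_n`` pairs with Q > 0 and N:P > 0,
    otherwise the site is ineligible (InsufficientDataError).
    """
    q = np.asarray(q, dtype=float)
    r = np.asarray(np_ratio, dtype=float)
    keep = np.isfinite(q) & np.isfinite(r) & (q > 0) & (r > 0)
    q, r = q[keep], r[keep]
    if q.size <= min_n:
        raise InsufficientDataError(
            f"site {site_id!r}: {q.size} usable records (need > {min_n})"
        )
    slope, intercept, p, se = _loglog_ols(np.log10(q), np.log10(r))
    return PowerLawFit(site_id, float(10.0 ** intercept), slope, int(q.size),
                       ratio_kind, p, se)


def site_power_laws(
    frame: pd.DataFrame,
    ratio_col: str,
    ratio_kind: str,
    q_col: str = "discharge_lps",
    min_n: int = 10,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-site power-law exponents; returns (fits table, ineligible sites)."""
    rows, ineligible = [], []
    for site, sub in frame.groupby("site_id", sort=True):
        try:
            fit = fit_power_law(sub[q_col], sub[ratio_col], ratio_kind, str(site), min_n)
        except InsufficientDataError:
            ineligible.append(str(site))
            continue
        except ValueError:  # zero variance in discharge
            ineligible.append(str(site))
            continue
        rows.append({"site_id": fit.site_id, "ratio_kind": ratio_kind,
                     "a_coeff": fit.a_coeff, "b_exp": fit.b_exp, "n": fit.n,
                     "p_value": fit.p_value})
    return pd.DataFrame(rows, columns=["site_id", "ratio_kind", "a_coeff", "b_exp",
                                       "n", "p_value"]), ineligible


_B_PREDICTORS = {
    "agriculture": lambda lu: lu["p_cro"] + lu["p_hay"],
    "urban": lambda lu: lu["p_urb"],
    "forest": lambda lu: lu["p_for"],
}


def regress_b_on_landuse(fits: pd.DataFrame, landuse: pd.DataFrame) -> pd.DataFrame:
    """Simple regressions of site b exponents on land-use proportions.

    One row per (ratio_kind, predictor) with slope and p-value; requires at
    least 10 sites with fits.  Degenerate predictors are flagged.
    """
    merged = fits.merge(landuse, on="site_id", how="inner")
    rows = []
    for kind, sub in merged.groupby("ratio_kind", sort=True):
        if len(sub) < 10:
            raise InsufficientDataError(
                f"ratio_kind {kind!r}: {len(sub)} sites with fits (need >= 10)"
            )
        for name, getter in _B_PREDICTORS.items():
            x = getter(sub).to_numpy(float)
            y = sub["b_exp"].to_numpy(float)
            if np.ptp(x) == 0.0:
                rows.append({"ratio_kind": kind, "predictor": name, "slope": np.nan,
                             "p_value": np.nan, "n_sites": len(sub), "degenerate": True})
                continue
            if np.ptp(y) == 0.0:
                rows.append({"ratio_kind": kind, "predictor": name, "slope": 0.0,
                             "p_value": 1.0, "n_sites": len(sub), "degenerate": False})
                continue
            fit = stats.linregress(x, y)
            rows.append({"ratio_kind": kind, "predictor": name,
                         "slope": float(fit.slope), "p_value": float(fit.pvalue),
                         "n_sites": len(sub), "degenerate": False})
    return pd.DataFrame(rows)
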