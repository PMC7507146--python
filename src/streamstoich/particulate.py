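"""Derivation of dissolved inorganic and particulate nutrient fractions.

DIN is the sum of ammonia-N (NH3-N + NH4-N) and nitrate+nitrite-N.  The
particulate fractions are obtained indirectly: the residual TN - DIN (or
TP - DIP) is split between dissolved organic and particulate matter using an
empirical distribution of the dissolved-organic share estimated from sites
with paired total / total-dissolved records,

    proportion = (TDN - DIN) / (TN - DIN)        (analogous for P),

i.e. the share of the residual that is dissolved organic.  For each record
the residual is multiplied by (1 - p_b) for n_boot proportions resampled
from that distribution; the particulate estimate is a single uniform draw
from the interquartile range of the bootstrapped candidates, which
propagates the DON/DOP uncertainty without committing to a single share.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream

__all__ = [
    "DomProportionDistribution",
    "compute_din",
    "add_din",
    "estimate_dom_proportions",
    "bootstrap_particulate",
    "derive_particulates",
    "filter_inconsistent",
    "check_dom_vs_landuse",
]


@dataclass
class DomProportionDistribution:
    """Empirical sample of the DON (or DOP) share of TN-DIN (or TP-DIP)."""

    analyte: str  # "N" or "P"
    proportions: np.ndarray  # values in [0, 1]
    n_source_pairs: int
    n_excluded: int = 0

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.size and (
            self.proportions.min() < 0 or self.proportions.max() > 1
        ):
            raise ValueError("proportions must lie in [0, 1]")

    @property
    def usable(self) -> bool:
        return self.proportions.size >= 10


def compute_din(nh3n, nh4n, no3no2n, strict: bool = False):
    """DIN = NH3-N + NH4-N + (NO3+NO2)-N, mg/L.

    Missing components are treated as 0 and flagged as a partial sum
    (``strict=True`` instead propagates NaN).  All components missing gives
    NaN.  Returns ``(din, partial_flag)``; works on scalars or arrays.
    """
    comps = [np.asarray(c, dtype=float) for c in (nh3n, nh4n, no3no2n)]
    missing = np.stack([np.isnan(c) for c in comps])
    all_missing = missing.all(axis=0)
    partial = missing.any(axis=0) & ~all_missing
    if strict:
        din = comps[0] + comps[1] + comps[2]
    else:
        din = np.nansum(np.stack(comps), axis=0)
        din = np.where(all_missing, np.nan, din)
    if np.ndim(nh3n) == 0 and np.ndim(nh4n) == 0 and np.ndim(no3no2n) == 0:
        return float(din), bool(partial)
    return din, partial


def add_din(frame: pd.DataFrame, strict: bool = False) -> pd.DataFrame:
    """Add ``din`` and ``din_partial`` columns computed from the components."""
    out = frame.copy()
    get = lambda c: frame[c].to_numpy(float) if c in frame.columns else np.full(len(frame), np.nan)
    din, partial = compute_din(get("NH3N"), get("NH4N"), get("NO3NO2N"), strict=strict)
    out["din"] = din
    out["din_partial"] = partial
    return out


def estimate_dom_proportions(frame: pd.DataFrame, analyte: str) -> DomProportionDistribution:
    """Estimate the dissolved-organic share distribution from paired records.

    For N requires TN, TDN and din columns: proportion = (TDN-DIN)/(TN-DIN);
    analogous for P with TP, TDP, DIP.  Proportions outside [0, 1] (including
    non-positive residuals) are excluded and counted.  Fewer than 10 valid
    pairs raises ValueError.
    """
    if analyte == "N":
        total, total_diss, inorganic = "TN", "TDN", "din"
    elif analyte == "P":
        total, total_diss, inorganic = "TP", "TDP", "DIP"
    else:
        raise ValueError("analyte must be 'N' or 'P'")
    cols = [total, total_diss, inorganic]
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"missing columns for {analyte} pairs: {missing}")
    tot = frame[total].to_numpy(float)
    tdis = frame[total_diss].to_numpy(float)
    dis = frame[inorganic].to_numpy(float)
    have = ~(np.isnan(tot) | np.isnan(tdis) | np.isnan(dis))
    residual = tot - dis
    with np.errstate(divide="ignore", invalid="ignore"):
        prop = (tdis - dis) / residual
    valid = have & (residual > 0) & (prop >= 0) & (prop <= 1)
    n_excluded = int(have.sum() - valid.sum())
    props = prop[valid]
    if props.size < 10:
        raise ValueError(
            f"insufficient pairs for {analyte}: {props.size} valid of {int(have.sum())}"
        )
    return DomProportionDistribution(analyte, props, int(have.sum()), n_excluded)


def bootstrap_particulate(
    residual: float,
    dist: DomProportionDistribution,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """One bootstrap-IQR estimate of the particulate concentration (mg/L).

    Resamples ``n_boot`` dissolved-organic shares with replacement, forms the
    candidates residual x (1 - p_b), and returns a single uniform draw within
    the candidates' interquartile range.  A non-positive draw means the
    residual is plausibly all dissolved organic: NaN is returned (callers
    count these).  A zero residual short-circuits to 0.
    """
    if not dist.usable:
        raise ValueError(f"DOM proportion distribution for {dist.analyte} unusable "
                         f"(n={dist.proportions.size} < 10)")
    if residual < 0:
        raise ValueError("residual must be >= 0 (apply filter_inconsistent first)")
    if residual == 0.0:
        return 0.0
    rng = rng or np.random.default_rng()
    idx = rng.integers(0, dist.proportions.size, n_boot)
    candidates = residual * (1.0 - dist.proportions[idx])
    q1, q3 = np.percentile(candidates, [25.0, 75.0])
    value = q1 if q1 == q3 else float(rng.uniform(q1, q3))
    return float(value) if value > 0 else np.nan


def derive_particulates(
    frame: pd.DataFrame,
    dist_n: DomProportionDistribution,
    dist_p: DomProportionDistribution,
    n_boot: int = 1000,
    seed: int = 0,
    realization: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Add bootstrap-derived ``pn`` and ``pp`` columns (mg/L).

    Each record gets an independent substream keyed on (seed, site, date,
    analyte, realization), so the derivation is bit-reproducible and
    insensitive to record order.  Returns the table and a missingness report
    counting records whose draw was non-positive (set to NaN).
    """
    out = frame.copy()
    report = {"pn_missing": 0, "pp_missing": 0, "pn_n": 0, "pp_n": 0}
    for name, total, inorganic, dist, code in (
        ("pn", "TN", "din", dist_n, 101),
        ("pp", "TP", "DIP", dist_p, 102),
    ):
        values = np.full(len(frame), np.nan)
        tot = frame[total].to_numpy(float) if total in frame.columns else np.full(len(frame), np.nan)
        dis = frame[inorganic].to_numpy(float) if inorganic in frame.columns else np.full(len(frame), np.nan)
        residual = tot - dis
        for pos, idx in enumerate(frame.index):
            r = residual[pos]
            if np.isnan(r):
                continue
            rng = substream(
                seed, "bootstrap", frame.at[idx, "site_id"], frame.at[idx, "date"],
                code, realization,
            )
            v = bootstrap_particulate(max(r, 0.0), dist, n_boot, rng)
            report[name + "_n"] += 1
            if np.isnan(v):
                report[name + "_missing"] += 1
            values[pos] = v
        out[name] = values
    return out, report


def filter_inconsistent(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove records whose dissolved inorganic fraction exceeds the total.

    Rows with DIN > TN or DIP > TP are removed; the report gives counts and
    fractions by analyte (denominator = rows where the pair is present).
    """
    n = len(frame)
    din = frame["din"].to_numpy(float) if "din" in frame.columns else np.full(n, np.nan)
    tn = frame["TN"].to_numpy(float) if "TN" in frame.columns else np.full(n, np.nan)
    dip = frame["DIP"].to_numpy(float) if "DIP" in frame.columns else np.full(n, np.nan)
    tp = frame["TP"].to_numpy(float) if "TP" in frame.columns else np.full(n, np.nan)
    pair_n = ~(np.isnan(din) | np.isnan(tn))
    pair_p = ~(np.isnan(dip) | np.isnan(tp))
    viol_n = pair_n & (din > tn)
    viol_p = pair_p & (dip > tp)
    removed = viol_n | viol_p
    report = pd.DataFrame(
        [
            {
                "analyte": "DIN",
                "n_pairs": int(pair_n.sum()),
                "n_removed": int(viol_n.sum()),
                "fraction": float(viol_n.sum() / pair_n.sum()) if pair_n.any() else np.nan,
            },
            {
                "analyte": "DIP",
                "n_pairs": int(pair_p.sum()),
                "n_removed": int(viol_p.sum()),
                "fraction": float(viol_p.sum() / pair_p.sum()) if pair_p.any() else np.nan,
            },
        ]
    )
    return frame.loc[~removed].reset_index(drop=True), report


def check_dom_vs_landuse(
    site_proportions: pd.Series | dict, landuse: pd.DataFrame
) -> pd.DataFrame:
    """Diagnostic regression of site-mean DOM share on each land-use proportion.

    Mirrors the gate the analysis applies before pooling DOM shares across
    sites: if the share depended on land use, a pooled distribution would
    bias land-use contrasts.  Returns one row per predictor with slope and
    two-sided p-value; a degenerate predictor is flagged with NaN slope.
    """
    props = pd.Series(site_proportions, dtype=float)
    merged = landuse.set_index("site_id").join(props.rename("prop"), how="inner").dropna(
        subset=["prop"]
    )
    if len(merged) < 3:
        raise ValueError(f"need >= 3 sites with proportions and land use, got {len(merged)}")
    rows = []
    for predictor in ("p_cro", "p_hay", "p_urb", "p_for"):
        x = merged[predictor].to_numpy(float)
        y = merged["prop"].to_numpy(float)
        if np.ptp(x) == 0.0:
            rows.append({"predictor": predictor, "slope": np.nan, "p_value": np.nan,
                         "n_sites": len(merged), "degenerate": True})
            continue
        if np.ptp(y) == 0.0:
            rows.append({"predictor": predictor, "slope": 0.0, "p_value": 1.0,
                         "n_sites": len(merged), "degenerate": False})
            continue
        fit = stats.linregress(x, y)
        rows.append({"predictor": predictor, "slope": float(fit.slope),
                     "p_value": float(fit.pvalue), "n_sites": len(merged),
                     "degenerate": False})
    return pd.DataFrame(rows)
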