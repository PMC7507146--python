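"""Molar ratios, threshold exceedance, descriptive summaries, percentile loess.

Molar N:P converts a mass ratio (mg N / mg P) by the ratio of molar masses,
(cn / 14.007) / (cp / 30.974), i.e. mass x 2.2113; the Redfield molar ratio
16:1 corresponds to a mass ratio of ~7.2.  Threshold comparisons use the
most conservative (highest) published response thresholds for ecosystem
structure (total nutrients) and half-saturation constants for ecosystem
function (dissolved nutrients), with strict ">" for "above".
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

N_MOLAR_MASS = 14.007  # g/mol
P_MOLAR_MASS = 30.974  # g/mol
#: multiply a mass N:P ratio by this to get the molar ratio
MASS_TO_MOLAR = P_MOLAR_MASS / N_MOLAR_MASS

__all__ = [
    "MASS_TO_MOLAR",
    "ThresholdSpec",
    "ExceedanceSummary",
    "PercentileCurve",
    "mass_to_molar_np",
    "builtin_thresholds",
    "thresholds_to_csv",
    "thresholds_from_csv",
    "exceedance_fraction",
    "exceedance_table",
    "summary_table",
    "percentile_loess",
]


def mass_to_molar_np(cn, cp):
    """Molar N:P from mass concentrations (mg/L as N, mg/L as P).

    cp = 0 (or missing) gives NaN.  Array-safe.
    """
    cn = np.asarray(cn, dtype=float)
    cp = np.asarray(cp, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(cp > 0, (cn / N_MOLAR_MASS) / (cp / P_MOLAR_MASS), np.nan)
    if ratio.ndim == 0:
        return float(ratio)
    return ratio


@dataclass(frozen=True)
class ThresholdSpec:
    analyte: str  # TN, TP, DIN, DIP
    response: str  # benthic_algae, macroinvertebrates, fish, litter_breakdown, algal_growth
    kind: str  # structural | functional_half_saturation
    value: float  # mg/L
    source: str = ""

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("threshold value must be > 0")


def builtin_thresholds() -> list[ThresholdSpec]:
    """The ten built-in response thresholds (mg/L).

    Structural thresholds (benthic algae, macroinvertebrates, fish) apply to
    total nutrients; functional half-saturation constants (litter breakdown,
    algal growth) apply to dissolved inorganic nutrients.
    """
    s, f = "structural", "functional_half_saturation"
    return [
        ThresholdSpec("TN", "benthic_algae", s, 1.162, "Evans-White et al. 2013"),
        ThresholdSpec("TP", "benthic_algae", s, 0.074, "Evans-White et al. 2013"),
        ThresholdSpec("TN", "macroinvertebrates", s, 1.92, "Evans-White et al. 2013"),
        ThresholdSpec("TP", "macroinvertebrates", s, 0.15, "Evans-White et al. 2013"),
        ThresholdSpec("TN", "fish", s, 1.83, "Evans-White et al. 2013"),
        ThresholdSpec("TP", "fish", s, 0.139, "Evans-White et al. 2013"),
        ThresholdSpec("DIN", "litter_breakdown", f, 0.052, "Kominoski et al. 2015"),
        ThresholdSpec("DIP", "litter_breakdown", f, 0.021, "Kominoski et al. 2015"),
        ThresholdSpec("DIN", "algal_growth", f, 0.186, "Schmidt et al."),
        ThresholdSpec("DIP", "algal_growth", f, 0.004, "Schmidt et al."),
    ]


def thresholds_to_csv(thresholds: Iterable[ThresholdSpec], path) -> None:
    pd.DataFrame([t.__dict__ for t in thresholds]).to_csv(path, index=False)


def thresholds_from_csv(path) -> list[ThresholdSpec]:
    df = pd.read_csv(path, comment="#")
    return [
        ThresholdSpec(r.analyte, r.response, r.kind, float(r.value), str(r.source))
        for r in df.itertuples()
    ]


@dataclass(frozen=True)
class ExceedanceSummary:
    threshold: ThresholdSpec
    n: int
    n_exceed: int

    @property
    def fraction(self) -> float:
        return self.n_exceed / self.n


def exceedance_fraction(values, threshold: ThresholdSpec) -> ExceedanceSummary:
    """Fraction of non-missing values strictly above the threshold."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no non-missing values to compare against threshold")
    return ExceedanceSummary(threshold, int(v.size), int((v > threshold.value).sum()))


_THRESHOLD_COLUMNS = {"TN": "TN", "TP": "TP", "DIN": "din", "DIP": "DIP"}


def exceedance_table(
    frame: pd.DataFrame, thresholds: Sequence[ThresholdSpec] | None = None
) -> pd.DataFrame:
    """Exceedance summaries for every threshold with data in the table."""
    thresholds = builtin_thresholds() if thresholds is None else thresholds
    rows = []
    for t in thresholds:
        col = _THRESHOLD_COLUMNS.get(t.analyte, t.analyte)
        if col not in frame.columns or frame[col].notna().sum() == 0:
            continue
        s = exceedance_fraction(frame[col], t)
        rows.append(
            {
                "analyte": t.analyte,
                "response": t.response,
                "kind": t.kind,
                "threshold_mg_l": t.value,
                "n": s.n,
                "n_exceed": s.n_exceed,
                "fraction": s.fraction,
            }
        )
    return pd.DataFrame(rows)


def developed_percent(frame: pd.DataFrame) -> pd.Series:
    """Developed land = % agriculture (crop + hay) + % urban."""
    return 100.0 * (frame["p_cro"] + frame["p_hay"] + frame["p_urb"])


def summary_table(
    frame: pd.DataFrame,
    columns: Sequence[str],
    developed_bins: Sequence[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Medians and interquartile ranges per column, overall and by land-use bin.

    Quartiles use linear interpolation (numpy/R type-7).  Bins are closed
    intervals on developed land-use percent, e.g. (5, 15) and (85, 95).
    """
    subsets: list[tuple[str, pd.DataFrame]] = [("all", frame)]
    if developed_bins:
        dev = developed_percent(frame)
        for lo, hi in developed_bins:
            subsets.append((f"developed_{lo:g}-{hi:g}%", frame[(dev >= lo) & (dev <= hi)]))
    rows = []
    for label, sub in subsets:
        for col in columns:
            if col not in sub.columns:
                continue
            v = sub[col].to_numpy(float)
            v = v[~np.isnan(v)]
            if v.size == 0:
                continue
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            rows.append(
                {"subset": label, "variable": col, "n": int(v.size),
                 "median": float(med), "q1": float(q1), "q3": float(q3)}
            )
    return pd.DataFrame(rows)


@dataclass
class PercentileCurve:
    percentile: float
    x: np.ndarray = field(repr=False)  # developed-land % grid
    y: np.ndarray = field(repr=False)  # smoothed concentration mg/L


def percentile_loess(
    x,
    y,
    percentiles: Sequence[float] = (10, 25, 50, 75, 90),
    window_halfwidth: float = 5.0,
    span: float = 0.75,
    grid_step: float = 1.0,
    min_points: int = 10,
) -> tuple[list[PercentileCurve], list[float]]:
    """Loess curves through running percentiles of y along x.

    At each grid point the empirical percentiles of y within the x-window
    (half-width in x units) are computed, then each percentile series is
    smoothed with locally weighted linear regression (tricube weights, the
    given span, no robustness iterations so the smoother is linear in y and
    cannot cross ordered series).  Grid points whose window holds fewer than
    ``min_points`` observations are omitted and returned separately.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 30:
        raise ValueError(f"need >= 30 points, got {x.size}")
    grid = np.arange(np.floor(x.min()), np.ceil(x.max()) + grid_step / 2, grid_step)
    retained, omitted = [], []
    series = {p: [] for p in percentiles}
    for g in grid:
        window = y[np.abs(x - g) <= window_halfwidth]
        if window.size < min_points:
            omitted.append(float(g))
            continue
        retained.append(float(g))
        for p in percentiles:
            series[p].append(np.percentile(window, p))
    if not retained:
        raise ValueError("every grid window was sparser than min_points")
    gx = np.asarray(retained)
    curves = []
    for p in percentiles:
        raw = np.asarray(series[p])
        if gx.size > 2:
            smooth = sm.nonparametric.lowess(
                raw, gx, frac=span, it=0, return_sorted=False
            )
        else:
            smooth = raw
        curves.append(PercentileCurve(float(p), gx.copy(), np.asarray(smooth)))
    return curves, omitted
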