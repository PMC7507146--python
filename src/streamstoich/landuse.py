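"""Random-intercept land-use models for nutrient concentrations.

Each concentration response (log10 TN, DIN, PN, TP, DIP, PP) is modelled as

    response ~ log10 Q + pCRO + pHAY + pFOR + pURB + (1 | site)

fitted by restricted maximum likelihood, where the land-use predictors are
watershed proportions and the random intercept absorbs site-level spatial /
temporal non-independence.  Standardized coefficients (raw x sd of the
predictor, equivalent to refitting on z-scored predictors) allow direct
comparison across predictors, and marginal / conditional R2 follow the
Nakagawa-Schielzeth variance decomposition for Gaussian models.  Inference
is Wald (95% CIs and p-values).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CoefEstimate",
    "LandUseModelFit",
    "CONCENTRATION_PREDICTORS",
    "fit_landuse_model",
    "standardize_predictors",
    "r2_mixed",
    "fraction_particulate_model",
]

CONCENTRATION_PREDICTORS = ("log10_q", "p_cro", "p_hay", "p_for", "p_urb")


class CoefEstimate(NamedTuple):
    estimate: float
    std_estimate: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class LandUseModelFit:
    response: str
    coefficients: dict[str, CoefEstimate]
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_sites: int
    site_sd: float
    resid_sd: float
    singular: bool = False
    converged: bool = True
    n_excluded: int = 0

    def to_row(self) -> dict:
        row: dict = {"response": self.response, "n_obs": self.n_obs,
                     "n_sites": self.n_sites}
        for name, c in self.coefficients.items():
            row[name] = c.estimate
            if name != "intercept":
                row[name + "_std"] = c.std_estimate
            row[name + "_p"] = c.p_value
        row["r2_marginal"] = self.r2_marginal
        row["r2_conditional"] = self.r2_conditional
        row["singular"] = self.singular
        return row


def standardize_predictors(
    frame: pd.DataFrame, predictors: Sequence[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Z-score predictors (sample sd, n-1); responses untouched.

    Constant columns are excluded with a warning and listed.
    """
    out = frame.copy()
    excluded = []
    for col in predictors:
        sd = out[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"predictor {col!r} has zero variance; excluded")
            excluded.append(col)
            out = out.drop(columns=[col])
            continue
        out[col] = (out[col] - out[col].mean()) / sd
    return out, excluded


def r2_mixed(result) -> tuple[float, float]:
    """Nakagawa-Schielzeth marginal and conditional R2 for a MixedLM fit.

    marginal    = var(fixed) / (var(fixed) + var(site) + var(resid))
    conditional = (var(fixed) + var(site)) / same denominator
    """
    fe = np.asarray(result.fe_params)
    X = result.model.exog
    var_fixed = float(np.var(X @ fe))
    var_site = float(np.asarray(result.cov_re)[0, 0])
    var_resid = float(result.scale)
    denom = var_fixed + var_site + var_resid
    return var_fixed / denom, (var_fixed + var_site) / denom


def _fit_mixed(
    frame: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    group_col: str = "site_id",
) -> LandUseModelFit:
    cols = [response, *predictors, group_col]
    data = frame[cols].dropna()
    n_excluded = len(frame) - len(data)
    n_sites = data[group_col].nunique()
    if n_sites < 2:
        raise ValueError(f"need >= 2 sites, got {n_sites}")
    y = data[response].to_numpy(float)

    sds = {p: float(data[p].std(ddof=1)) for p in predictors}

    if np.ptp(y) < 1e-12:
        # Degenerate constant response: every slope is 0 by construction.
        coefs = {"intercept": CoefEstimate(float(y[0]), np.nan, float(y[0]), float(y[0]), np.nan)}
        for p in predictors:
            coefs[p] = CoefEstimate(0.0, 0.0, 0.0, 0.0, 1.0)
        return LandUseModelFit(response, coefs, 0.0, 0.0, len(data), n_sites,
                               0.0, 0.0, singular=True, n_excluded=n_excluded)

    X = sm.add_constant(data[list(predictors)].to_numpy(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=data[group_col].to_numpy())
        result = model.fit(reml=True)
    params = np.asarray(result.fe_params)
    conf = np.asarray(result.conf_int())[: len(params)]
    pvals = np.asarray(result.pvalues)[: len(params)]
    names = ["intercept", *predictors]
    coefs = {}
    for i, name in enumerate(names):
        std = params[i] * sds[name] if name in sds else np.nan
        coefs[name] = CoefEstimate(float(params[i]), float(std) if name in sds else np.nan,
                                   float(conf[i, 0]), float(conf[i, 1]), float(pvals[i]))
    var_site = float(np.asarray(result.cov_re)[0, 0])
    r2m, r2c = r2_mixed(result)
    return LandUseModelFit(
        response, coefs, r2m, r2c, len(data), int(n_sites),
        site_sd=float(np.sqrt(max(var_site, 0.0))),
        resid_sd=float(np.sqrt(result.scale)),
        singular=var_site < 1e-8,
        converged=bool(getattr(result, "converged", True)),
        n_excluded=n_excluded,
    )


def fit_landuse_model(
    frame: pd.DataFrame,
    response: str,
    predictors: Sequence[str] = CONCENTRATION_PREDICTORS,
    group_col: str = "site_id",
) -> LandUseModelFit:
    """Fit the random-intercept land-use model for one response column.

    ``frame`` must carry the response, ``log10_q``, the land-use proportion
    columns and ``site_id``.  Complete-case per response.  A site variance
    collapsing to ~0 is retained but flagged singular.
    """
    return _fit_mixed(frame, response, predictors, group_col)


def fraction_particulate_model(
    frame: pd.DataFrame, analyte: str = "N", group_col: str = "site_id"
) -> LandUseModelFit:
    """Mixed model for the percent of the total nutrient held in particles.

    Response = 100 x PN/TN (or PP/TP); predictors are land-use percentages
    (so a slope of -0.02 means a 0.02 percentage-point drop of %particulate
    per 1% more of that land use) plus log10 discharge; random site
    intercept.  Records with a zero or missing total are excluded.
    """
    if analyte == "N":
        part, total = "pn", "TN"
    elif analyte == "P":
        part, total = "pp", "TP"
    else:
        raise ValueError("analyte must be 'N' or 'P'")
    data = frame.copy()
    tot = data[total].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        resp = np.where(tot > 0, 100.0 * data[part].to_numpy(float) / tot, np.nan)
    data[f"pct_particulate_{analyte}"] = resp
    for p in ("cro", "hay", "for", "urb"):
        data[f"pct_{p}"] = 100.0 * data[f"p_{p}"]
    predictors = ("log10_q", "pct_cro", "pct_hay", "pct_for", "pct_urb")
    return _fit_mixed(data, f"pct_particulate_{analyte}", predictors, group_col)


def landuse_model_table(fits: Sequence[LandUseModelFit]) -> pd.DataFrame:
    """One row per fitted response, in the shape of a model-summary table."""
    return pd.DataFrame([f.to_row() for f in fits])
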