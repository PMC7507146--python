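"""Synthetic multi-site stream-chemistry panels with full ground truth.

The generator emulates the statistical structure the analysis assumes:

* site land-use proportions drawn from a Dirichlet over (crop, hay, urban,
  forest, other), watershed areas lognormal;
* lognormal discharge, independent of land use by default;
* log10 dissolved inorganic N and P and log10 particulate N follow linear
  models in land-use proportions and log10 Q with Gaussian site intercepts
  and residuals (default coefficients keyed to continental-scale stream
  monitoring estimates);
* the particulate molar N:P ratio is coupled to the dissolved molar N:P by
  log10(PN:PP) = true_log_c + true_inv_h x log10(DIN:DIP) + noise, and PP is
  solved from PN and the ratio, so the imposed homeostasis slope is exactly
  the quantity the analysis estimates;
* dissolved organic fractions arise from Beta-distributed shares of the
  TN-DIN (TP-DIP) residual, giving exact mass closure
  TN = DIN + DON + PN and TP = DIP + DOP + PP on every record;
* detection-limit and "estimated" qualifiers are injected afterwards, with
  truth retained in a sidecar table.

Generation order (dissolved -> organic share -> particulate ratio -> PP) is
fixed so every downstream estimator has a well-defined generator truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .metrics import MASS_TO_MOLAR

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_landscape",
           "generate_samples", "inject_censoring", "generate_dataset"]


def _default_effects() -> dict[str, dict[str, float]]:
    # log10 mg/L per unit proportion (land use) or per log10 L/s (q).
    return {
        "din": {"intercept": -1.092, "q": 0.162, "p_cro": 1.183, "p_hay": 1.205,
                "p_for": -0.469, "p_urb": 1.025},
        "dip": {"intercept": -1.515, "q": 0.003, "p_cro": 0.399, "p_hay": 0.346,
                "p_for": -0.983, "p_urb": 0.332},
        "pn": {"intercept": -1.561, "q": 0.088, "p_cro": 0.226, "p_hay": 0.060,
               "p_for": -0.979, "p_urb": 0.111},
    }


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of the synthetic world.

    All concentration scales are log10 mg/L; discharge is L/s; proportions
    are fractions of the watershed.
    """

    n_sites: int = 200
    obs_per_site: int = 20
    #: extra sites with long sequential records (>100 samples), mirroring the
    #: kind of decade-scale monitoring subset used for per-site homeostasis.
    n_timeseries_sites: int = 13
    timeseries_obs: int = 150
    #: Dirichlet over (crop, hay, urban, forest, other); low total
    #: concentration gives realistically sparse, wide-spread land-use mixes.
    landuse_concentration: tuple[float, ...] = (0.27, 0.18, 0.21, 0.375, 0.465)
    area_logmean: float = 2.85  # log10 km^2 (median ~700 km^2)
    area_logsd: float = 1.0
    discharge_logmean: float = 3.0  # log10 L/s
    discharge_logsd: float = 0.8
    effects: dict = field(default_factory=_default_effects)
    site_sd: float = 0.12  # log10 mg/L, site random intercepts
    resid_sd: float = 0.2  # log10 mg/L, within-site residual
    dom_beta_n: tuple[float, float] = (4.0, 2.0)  # DON share of TN-DIN
    dom_beta_p: tuple[float, float] = (2.0, 4.0)  # DOP share of TP-DIP
    true_inv_h: float = 0.096
    true_log_c: float = 0.434
    np_resid_sd: float = 0.25  # log10, residual of the PN:PP ~ DIN:DIP coupling
    site_inv_h: Sequence[float] | None = None  # optional per-site 1/H override
    nh3_fraction: float = 0.05  # share of DIN reported as ammonia-N
    detection_limits: Mapping[str, float] = field(
        default_factory=lambda: {"NH3N": 0.01, "NO3NO2N": 0.04, "DIP": 0.002}
    )
    censor_estimated_rate: float = 0.05
    start_date: str = "2003-09-01"
    sample_interval_days: int = 30
    seed: int = 0

    def __post_init__(self):
        for name in ("site_sd", "resid_sd", "np_resid_sd", "discharge_logsd", "area_logsd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.censor_estimated_rate <= 1:
            raise ValueError("censor_estimated_rate must be in [0, 1]")
        if any(a <= 0 for a in self.landuse_concentration):
            raise ValueError("Dirichlet concentration parameters must be > 0")
        for pair in (self.dom_beta_n, self.dom_beta_p):
            if any(a <= 0 for a in pair):
                raise ValueError("Beta shape parameters must be > 0")


@dataclass
class SyntheticDataset:
    samples: pd.DataFrame  # ingest-dialect wide table with qualifier columns
    landscape: pd.DataFrame  # site_id, p_cro..p_other, watershed_area_km2
    truth: pd.DataFrame  # per-record true concentrations
    site_truth: pd.DataFrame  # per-site intercepts and true 1/H
    config: SyntheticConfig


def generate_landscape(config: SyntheticConfig) -> pd.DataFrame:
    """Draw per-site land-use proportions and watershed areas."""
    n_total = config.n_sites + config.n_timeseries_sites
    if n_total < 1:
        raise ValueError("need at least one site")
    rng = substream(config.seed, "synthetic", "landscape")
    props = rng.dirichlet(np.asarray(config.landuse_concentration, float), size=n_total)
    areas = 10.0 ** rng.normal(config.area_logmean, config.area_logsd, size=n_total)
    site_ids = [f"S{i:04d}" for i in range(n_total)]
    return pd.DataFrame(
        {
            "site_id": site_ids,
            "p_cro": props[:, 0],
            "p_hay": props[:, 1],
            "p_urb": props[:, 2],
            "p_for": props[:, 3],
            "p_other": props[:, 4],
            "watershed_area_km2": areas,
        }
    )


def generate_samples(
    profiles: pd.DataFrame, config: SyntheticConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate uncensored samples plus per-record and per-site truth tables.

    Returns (samples, truth, site_truth).  Samples carry the ingest analyte
    columns (ammonia reported as a combined NH3N column); TDN/TDP are
    included on every record so organic-share distributions can be estimated
    from the same table.
    """
    if profiles.empty:
        raise ValueError("profiles is empty")
    rng = substream(config.seed, "synthetic", "samples")
    n_sites = len(profiles)
    intercepts = {
        resp: rng.normal(0.0, config.site_sd, size=n_sites) for resp in ("din", "dip", "pn")
    }
    if config.site_inv_h is not None:
        site_inv_h = np.asarray(list(config.site_inv_h), dtype=float)
        if site_inv_h.size != n_sites:
            raise ValueError("site_inv_h length must equal the number of sites")
    else:
        site_inv_h = np.full(n_sites, config.true_inv_h)

    obs_counts = np.full(n_sites, config.obs_per_site)
    if config.n_timeseries_sites:
        obs_counts[-config.n_timeseries_sites:] = config.timeseries_obs

    site_idx = np.repeat(np.arange(n_sites), obs_counts)
    n = site_idx.size
    start = pd.Timestamp(config.start_date)
    seq_within = np.concatenate([np.arange(c) for c in obs_counts])
    dates = start + pd.to_timedelta(seq_within * config.sample_interval_days, unit="D")

    log_q = rng.normal(config.discharge_logmean, config.discharge_logsd, size=n)
    q = 10.0 ** log_q

    lu = profiles.iloc[site_idx]
    conc = {}
    for resp in ("din", "dip", "pn"):
        eff = config.effects[resp]
        mean = (
            eff["intercept"]
            + eff["q"] * log_q
            + eff["p_cro"] * lu["p_cro"].to_numpy()
            + eff["p_hay"] * lu["p_hay"].to_numpy()
            + eff["p_for"] * lu["p_for"].to_numpy()
            + eff["p_urb"] * lu["p_urb"].to_numpy()
            + intercepts[resp][site_idx]
        )
        conc[resp] = 10.0 ** (mean + rng.normal(0.0, config.resid_sd, size=n))

    din, dip, pn = conc["din"], conc["dip"], conc["pn"]
    molar_dissolved = MASS_TO_MOLAR * din / dip
    log_pnpp = (
        config.true_log_c
        + site_inv_h[site_idx] * np.log10(molar_dissolved)
        + rng.normal(0.0, config.np_resid_sd, size=n)
    )
    pp = MASS_TO_MOLAR * pn / (10.0 ** log_pnpp)

    p_don = rng.beta(*config.dom_beta_n, size=n)
    p_dop = rng.beta(*config.dom_beta_p, size=n)
    don = p_don / (1.0 - p_don) * pn
    dop = p_dop / (1.0 - p_dop) * pp

    tn = din + don + pn
    tp = dip + dop + pp

    samples = pd.DataFrame(
        {
            "site_id": profiles["site_id"].to_numpy()[site_idx],
            "date": dates,
            "discharge_lps": q,
            "NH3N": config.nh3_fraction * din,
            "NO3NO2N": (1.0 - config.nh3_fraction) * din,
            "DIP": dip,
            "TN": tn,
            "TP": tp,
            "TDN": din + don,
            "TDP": dip + dop,
        }
    )
    truth = pd.DataFrame(
        {
            "site_id": samples["site_id"],
            "date": dates,
            "discharge_lps": q,
            "din": din,
            "don": don,
            "pn": pn,
            "dip": dip,
            "dop": dop,
            "pp": pp,
            "tn": tn,
            "tp": tp,
            "p_don": p_don,
            "p_dop": p_dop,
        }
    )
    site_truth = pd.DataFrame(
        {
            "site_id": profiles["site_id"].to_numpy(),
            "intercept_din": intercepts["din"],
            "intercept_dip": intercepts["dip"],
            "intercept_pn": intercepts["pn"],
            "inv_h": site_inv_h,
        }
    )
    return samples, truth, site_truth


def inject_censoring(samples: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Apply detection-limit and "estimated" qualifiers in place of truth.

    Values below an analyte's detection limit become less-than records at
    the limit; a random ``censor_estimated_rate`` fraction of the remaining
    values of limit-bearing analytes become "estimated" (value unchanged).
    """
    rng = substream(config.seed, "synthetic", "censoring")
    out = samples.copy()
    for analyte in ("NH3N", "NH4N", "NO3NO2N", "DIP", "TN", "TP", "TDN", "TDP"):
        if analyte not in out.columns:
            continue
        qcol = analyte + "_qual"
        values = out[analyte].to_numpy(float)
        quals = np.where(np.isnan(values), None, "measured").astype(object)
        limit = config.detection_limits.get(analyte)
        if limit:
            below = values < limit
            values = np.where(below, limit, values)
            quals[below] = "less_than"
            remaining = ~below & ~np.isnan(values)
            est = remaining & (rng.random(len(values)) < config.censor_estimated_rate)
            quals[est] = "estimated"
        out[analyte] = values
        out[qcol] = quals
    return out


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Landscape -> samples -> censoring, returning data plus full truth."""
    config = config or SyntheticConfig()
    landscape = generate_landscape(config)
    samples, truth, site_truth = generate_samples(landscape, config)
    censored = inject_censoring(samples, config)
    return SyntheticDataset(censored, landscape, truth, site_truth, config)
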