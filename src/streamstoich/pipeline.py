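"""Configuration-driven end-to-end runner.

Executes ingest -> censoring imputation -> DIN / consistency filter ->
organic-share estimation -> bootstrap particulate derivation -> ratio and
threshold metrics -> homeostasis and discharge power laws -> land-use mixed
models, from either real CSV inputs or the synthetic generator, and writes
a bundle of CSV outputs plus a JSON run manifest.  Re-running with the same
config and seed reproduces every output byte-for-byte: all randomness flows
from the single seed through keyed substreams and no output embeds a
timestamp.
"""
from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .censoring import CensoringPolicy, impute_table
from .homeostasis import (
    InsufficientDataError,
    fit_homeostasis,
    fit_homeostasis_by_tp_bin,
    per_site_homeostasis,
    regress_b_on_landuse,
    site_power_laws,
)
from .ingest import IngestSchema, join_site_data, read_landuse_table, read_sample_table, landuse_to_frame
from .landuse import fit_landuse_model, fraction_particulate_model, landuse_model_table
from .metrics import (
    builtin_thresholds,
    developed_percent,
    exceedance_table,
    mass_to_molar_np,
    percentile_loess,
    summary_table,
    thresholds_from_csv,
)
from .particulate import (
    add_din,
    check_dom_vs_landuse,
    derive_particulates,
    estimate_dom_proportions,
    filter_inconsistent,
)
from .simulate import SyntheticConfig, generate_dataset

__all__ = ["ConfigError", "default_config", "validate_config", "run_pipeline", "RunResult"]


class ConfigError(ValueError):
    pass


def default_config() -> dict:
    """The full default configuration (synthetic mode)."""
    return {
        "seed": None,  # mandatory
        "output_dir": "streamstoich_out",
        "realizations": 1,
        "synthetic": {},  # SyntheticConfig field overrides
        "inputs": None,  # {"samples": path, "landuse": path} for real data
        "censoring": {"cv_estimated": 0.10, "lower_bound_lt": 0.0},
        "bootstrap": {"n_boot": 1000},
        "thresholds": None,  # optional CSV registry path
        "landuse_bins": [[5, 15], [85, 95]],
        "homeostasis": {"tp_low": 0.025, "tp_high": 0.10, "min_site_n": 100},
        "power_law": {"min_n": 10},
        "loess": {"window_halfwidth": 5.0, "span": 0.75, "grid_step": 1.0, "min_points": 10},
    }


_SYNTH_KEYS = set(SyntheticConfig.__dataclass_fields__) - {"seed"}
_INPUT_KEYS = {"samples", "landuse"}


def _check_keys(given: dict, allowed: set, context: str, errors: list[str]) -> None:
    for key in given:
        if key not in allowed:
            errors.append(f"unknown key {key!r} in {context}")


def validate_config(config, seed: int | None = None) -> dict:
    """Validate and resolve a config (dict or YAML path) against defaults.

    Unknown keys are rejected; exactly one of real inputs / synthetic block
    must be active; a seed is mandatory (the ``seed`` argument overrides the
    file).  Returns the fully materialized config.  Raises ConfigError with
    every problem listed.
    """
    if not isinstance(config, dict):
        path = Path(config)
        try:
            with open(path) as fh:
                config = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            where = f" at line {mark.line + 1}" if mark else ""
            raise ConfigError(f"malformed YAML in {path}{where}: {exc}") from None
        if not isinstance(config, dict):
            raise ConfigError(f"config root in {path} must be a mapping")
    errors: list[str] = []
    defaults = default_config()
    _check_keys(config, set(defaults), "config", errors)
    resolved = copy.deepcopy(defaults)
    for key, value in config.items():
        if key in resolved:
            if isinstance(resolved[key], dict) and isinstance(value, dict):
                resolved[key].update(value)
            else:
                resolved[key] = copy.deepcopy(value)
    if seed is not None:
        resolved["seed"] = int(seed)
    if resolved["seed"] is None:
        errors.append("seed is mandatory (set it in the config or pass --seed)")
    if resolved.get("synthetic") is not None:
        _check_keys(resolved["synthetic"], _SYNTH_KEYS, "synthetic", errors)
    if resolved.get("inputs") is not None:
        _check_keys(resolved["inputs"], _INPUT_KEYS, "inputs", errors)
        missing = _INPUT_KEYS - set(resolved["inputs"])
        if missing:
            errors.append(f"inputs requires keys {sorted(missing)}")
    real = resolved.get("inputs") is not None
    synthetic = resolved.get("synthetic") is not None
    if real == synthetic:
        errors.append("exactly one of 'inputs' (real data) or 'synthetic' must be active; "
                      "set the other to null")
    if resolved["bootstrap"].get("n_boot", 0) < 1:
        errors.append("bootstrap.n_boot must be >= 1")
    if resolved["realizations"] < 1:
        errors.append("realizations must be >= 1")
    if resolved["censoring"].get("cv_estimated", 0) < 0:
        errors.append("censoring.cv_estimated must be >= 0")
    if errors:
        raise ConfigError("; ".join(errors))
    return resolved


@dataclass
class RunResult:
    out_dir: Path
    outputs: dict[str, Path]
    manifest: dict
    tables: dict[str, pd.DataFrame]


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, stamp: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# {stamp}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config, out_dir=None, seed: int | None = None) -> RunResult:
    """Run the full analysis; see module docstring for the stage order."""
    cfg = validate_config(config, seed=seed)
    out = Path(out_dir if out_dir is not None else cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"streamstoich {__version__} config={_config_hash(cfg)[:12]}"
    log_lines: list[str] = [stamp]
    counts: dict[str, int] = {}
    tables: dict[str, pd.DataFrame] = {}
    the_seed = int(cfg["seed"])

    def log(msg: str) -> None:
        log_lines.append(msg)

    # ---- stage: inputs -------------------------------------------------
    if cfg["inputs"] is not None:
        result = read_sample_table(cfg["inputs"]["samples"], IngestSchema())
        samples = result.frame
        counts["rejects"] = len(result.rejects)
        tables["rejects"] = result.rejects
        landuse = landuse_to_frame(read_landuse_table(cfg["inputs"]["landuse"]))
        log(f"ingest: {len(samples)} records, {counts['rejects']} rejects")
    else:
        synth = SyntheticConfig(seed=the_seed, **cfg["synthetic"])
        dataset = generate_dataset(synth)
        samples, landuse = dataset.samples, dataset.landscape
        counts["rejects"] = 0
        tables["truth"] = dataset.truth
        _write_csv(dataset.truth, out / "truth.csv", stamp)
        log(f"synthetic: {len(samples)} records at {len(landuse)} sites")
    counts["records_in"] = len(samples)

    joined = join_site_data(samples, landuse)
    counts["orphans"] = joined.n_orphans
    counts["joined"] = len(joined.frame)
    log(f"join: {counts['joined']} joined, {counts['orphans']} orphans")

    policy = CensoringPolicy(seed=the_seed, **cfg["censoring"])
    n_boot = int(cfg["bootstrap"]["n_boot"])
    realizations = int(cfg["realizations"])

    derived_parts = []
    for r in range(realizations):
        imputed, imp_log = impute_table(joined.frame, policy, seed=the_seed, realization=r)
        if r == 0:
            tables["imputation_log"] = imp_log
            _write_csv(imp_log, out / "imputation_log.csv", stamp)
            counts["imputed_cells"] = int(imp_log["n_imputed"].sum()) if len(imp_log) else 0
        with_din = add_din(imputed)
        filtered, removal = filter_inconsistent(with_din)
        if r == 0:
            tables["removal_report"] = removal
            _write_csv(removal, out / "removal_report.csv", stamp)
            counts["removed_inconsistent"] = counts["joined"] - len(filtered)
        dist_n = estimate_dom_proportions(filtered, "N")
        dist_p = estimate_dom_proportions(filtered, "P")
        if r == 0:
            counts["dom_pairs_n"] = dist_n.n_source_pairs
            counts["dom_pairs_p"] = dist_p.n_source_pairs
            log(
                f"dom proportions: N {dist_n.proportions.size} retained "
                f"({dist_n.n_excluded} excluded), P {dist_p.proportions.size} retained "
                f"({dist_p.n_excluded} excluded)"
            )
            # diagnostic gate: organic shares should not track land use
            with np.errstate(divide="ignore", invalid="ignore"):
                prop_n = (filtered["TDN"] - filtered["din"]) / (filtered["TN"] - filtered["din"])
            prop_n = prop_n.where((prop_n >= 0) & (prop_n <= 1))
            site_mean = prop_n.groupby(filtered["site_id"]).mean().dropna()
            if len(site_mean) >= 3:
                dom_check = check_dom_vs_landuse(site_mean, landuse)
                tables["dom_landuse_check"] = dom_check
                _write_csv(dom_check, out / "dom_landuse_check.csv", stamp)
        part, missing_report = derive_particulates(
            filtered, dist_n, dist_p, n_boot=n_boot, seed=the_seed, realization=r
        )
        if r == 0:
            counts.update(missing_report)
        part["realization"] = r
        derived_parts.append(part)
    derived = pd.concat(derived_parts, ignore_index=True)

    # ---- stage: derived ratios -----------------------------------------
    derived["np_total"] = mass_to_molar_np(derived["TN"], derived["TP"])
    derived["np_dissolved"] = mass_to_molar_np(derived["din"], derived["DIP"])
    derived["np_particulate"] = mass_to_molar_np(derived["pn"], derived["pp"])
    with np.errstate(divide="ignore", invalid="ignore"):
        derived["log10_q"] = np.where(
            derived["discharge_lps"] > 0, np.log10(derived["discharge_lps"]), np.nan
        )
        for col, name in (("TN", "tn"), ("din", "din"), ("pn", "pn"),
                          ("TP", "tp"), ("DIP", "dip"), ("pp", "pp")):
            v = derived[col].to_numpy(float)
            derived[f"log10_{name}"] = np.where(v > 0, np.log10(v), np.nan)
    tables["derived"] = derived
    _write_csv(derived, out / "derived.csv", stamp)
    first = derived[derived["realization"] == 0]

    # ---- stage: metrics -------------------------------------------------
    thresholds = (
        thresholds_from_csv(cfg["thresholds"]) if cfg["thresholds"] else builtin_thresholds()
    )
    exceed = exceedance_table(derived, thresholds)
    tables["exceedance"] = exceed
    _write_csv(exceed, out / "exceedance.csv", stamp)

    ratio_cols = ["TN", "din", "pn", "TP", "DIP", "pp",
                  "np_total", "np_dissolved", "np_particulate"]
    summary = summary_table(derived, ratio_cols,
                            developed_bins=[tuple(b) for b in cfg["landuse_bins"]])
    tables["summary"] = summary
    _write_csv(summary, out / "summary.csv", stamp)

    loess_cfg = cfg["loess"]
    dev = developed_percent(derived)
    curve_rows = []
    for col in ("TN", "din", "pn", "TP", "DIP", "pp"):
        values = derived[col]
        try:
            curves, omitted = percentile_loess(
                dev, values,
                window_halfwidth=loess_cfg["window_halfwidth"],
                span=loess_cfg["span"], grid_step=loess_cfg["grid_step"],
                min_points=loess_cfg["min_points"],
            )
        except ValueError as exc:
            log(f"loess {col}: skipped ({exc})")
            continue
        if omitted:
            log(f"loess {col}: {len(omitted)} sparse grid points omitted")
        for c in curves:
            for xv, yv in zip(c.x, c.y):
                curve_rows.append({"variable": col, "percentile": c.percentile,
                                   "developed_pct": xv, "value": yv})
    curves_df = pd.DataFrame(curve_rows)
    tables["percentile_curves"] = curves_df
    _write_csv(curves_df, out / "percentile_curves.csv", stamp)

    # ---- stage: homeostasis + power laws --------------------------------
    hcfg = cfg["homeostasis"]
    h_rows = []
    global_fit = fit_homeostasis(derived["np_dissolved"], derived["np_particulate"], "all")
    h_rows.append(global_fit.__dict__ | {"subset_label": "all"})
    for label, fit in fit_homeostasis_by_tp_bin(
        derived, tp_low=hcfg["tp_low"], tp_high=hcfg["tp_high"]
    ).items():
        if fit is not None:
            h_rows.append(fit.__dict__)
    homeo = pd.DataFrame(h_rows)
    tables["homeostasis"] = homeo
    _write_csv(homeo, out / "homeostasis.csv", stamp)

    site_fits, ineligible = per_site_homeostasis(first, min_n=hcfg["min_site_n"])
    if len(site_fits):
        site_fits = site_fits.merge(landuse, on="site_id", how="left")
    tables["site_homeostasis"] = site_fits
    _write_csv(site_fits, out / "site_homeostasis.csv", stamp)
    counts["sites_homeostasis_eligible"] = len(site_fits)
    log(f"per-site homeostasis: {len(site_fits)} eligible, {len(ineligible)} ineligible")

    pl_parts = []
    for kind, col in (("total", "np_total"), ("dissolved", "np_dissolved"),
                      ("particulate", "np_particulate")):
        fits, inel = site_power_laws(first, col, kind, min_n=cfg["power_law"]["min_n"])
        pl_parts.append(fits)
        log(f"power law {kind}: {len(fits)} sites fitted, {len(inel)} ineligible")
    power = pd.concat(pl_parts, ignore_index=True)
    tables["power_law"] = power
    _write_csv(power, out / "power_law.csv", stamp)
    try:
        b_landuse = regress_b_on_landuse(power, landuse)
    except InsufficientDataError as exc:
        log(f"power-law land-use regression skipped: {exc}")
        b_landuse = pd.DataFrame()
    tables["power_law_landuse"] = b_landuse
    _write_csv(b_landuse, out / "power_law_landuse.csv", stamp)

    # ---- stage: land-use mixed models -----------------------------------
    fits = []
    for resp in ("log10_tn", "log10_din", "log10_pn", "log10_tp", "log10_dip", "log10_pp"):
        fits.append(fit_landuse_model(first, resp))
    for analyte in ("N", "P"):
        fits.append(fraction_particulate_model(first, analyte))
    models = landuse_model_table(fits)
    tables["landuse_models"] = models
    _write_csv(models, out / "landuse_models.csv", stamp)

    # ---- manifest + log --------------------------------------------------
    manifest = {
        "pipeline": "streamstoich",
        "version": __version__,
        "seed": the_seed,
        "config": cfg,
        "config_sha256": _config_hash(cfg),
        "counts": counts,
        "global_inv_h": global_fit.slope_inv_h,
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    outputs = {p.stem: p for p in sorted(out.glob("*"))}
    return RunResult(out, outputs, manifest, tables)
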