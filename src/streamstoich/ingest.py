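"""Reading, validation and joining of water-chemistry and land-use tables.

The canonical in-memory representation is a wide pandas DataFrame with one
row per site x date sample and, for each analyte, a concentration column in
mg/L (as N or as P) plus a ``<analyte>_qual`` qualifier column taking the
values ``measured``, ``estimated`` or ``less_than``.  For a less-than record
the stored number is the reporting limit, not a concentration.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Analytes the pipeline understands, all as mg/L of N or P.
ANALYTES = ("NH3N", "NH4N", "NO3NO2N", "DIP", "TN", "TP", "TDN", "TDP")

QUAL_SUFFIX = "_qual"

_UNIT_FACTORS = {"mg/l": 1.0, "mg/L": 1.0, "ug/l": 1e-3, "ug/L": 1e-3, "µg/L": 1e-3}


class Qualifier(str, Enum):
    measured = "measured"
    estimated = "estimated"
    less_than = "less_than"


@dataclass(frozen=True)
class QualifiedValue:
    """A concentration with its reporting qualifier.

    For ``less_than`` the value is the reporting limit.
    """

    value: float
    qualifier: Qualifier = Qualifier.measured

    def __post_init__(self):
        if self.value < 0:
            raise ValueError(f"negative concentration: {self.value}")


@dataclass
class SampleRecord:
    """One site x date water-chemistry observation."""

    site_id: str
    timestamp: pd.Timestamp
    discharge_q: float | None = None  # L/s
    conc: dict[str, QualifiedValue] = field(default_factory=dict)


@dataclass(frozen=True)
class LandUseProfile:
    """Watershed land-use proportions for one monitoring site."""

    site_id: str
    p_cro: float
    p_hay: float
    p_urb: float
    p_for: float
    p_other: float
    watershed_area_km2: float

    def __post_init__(self):
        for name in ("p_cro", "p_hay", "p_urb", "p_for", "p_other"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 + 1e-9:
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = self.p_cro + self.p_hay + self.p_urb + self.p_for + self.p_other
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"land-use proportions sum to {total}, not 1")


@dataclass
class IngestSchema:
    """Column-name map for sample CSVs (defaults match the pipeline's own dialect).

    ``long_format=True`` switches to a one-row-per-result layout in the style
    of Water Quality Portal exports (site / date / analyte / value / qualifier
    columns).  A unit column (or per-analyte ``units`` map for wide tables)
    converts ug/L inputs explicitly; units are never guessed.
    """

    site: str = "site_id"
    date: str = "date"
    discharge: str | None = "discharge_lps"
    analytes: Mapping[str, str] = field(default_factory=lambda: {a: a for a in ANALYTES})
    qualifier_suffix: str = QUAL_SUFFIX
    units: Mapping[str, str] = field(default_factory=dict)
    long_format: bool = False
    analyte_col: str = "analyte"
    value_col: str = "value"
    qualifier_col: str | None = "qualifier"
    unit_col: str | None = None


@dataclass
class IngestResult:
    records: list[SampleRecord]
    rejects: pd.DataFrame  # columns: row, reason

    @property
    def frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


class ConfigurationError(ValueError):
    pass


def _parse_cell(raw, qualifier_hint: str | None, unit: str | None) -> QualifiedValue | None:
    """Parse one concentration cell; None for blank cells.

    Accepts plain numbers and ``"<limit>"`` strings (less-than records).
    Raises ValueError for negative or unparseable values.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    qualifier = Qualifier.measured
    if isinstance(raw, str):
        text = raw.strip()
        if not text:
            return None
        if text.startswith("<"):
            qualifier = Qualifier.less_than
            text = text[1:]
        value = float(text)
    else:
        value = float(raw)
    if np.isnan(value):
        return None
    if value < 0:
        raise ValueError("negative")
    if qualifier is Qualifier.measured and qualifier_hint:
        hint = str(qualifier_hint).strip().lower()
        if hint in ("estimated", "e", "est"):
            qualifier = Qualifier.estimated
        elif hint in ("less_than", "less than", "<", "lt", "nondetect"):
            qualifier = Qualifier.less_than
    if unit is not None:
        if unit not in _UNIT_FACTORS:
            raise ValueError(f"unknown unit {unit!r}")
        value *= _UNIT_FACTORS[unit]
    return QualifiedValue(value, qualifier)


def read_sample_table(path, schema: IngestSchema | None = None) -> IngestResult:
    """Read a sample CSV into SampleRecords.

    Unparseable rows are collected in ``rejects`` with a reason code, never
    silently dropped.  A missing required column raises ConfigurationError.
    """
    schema = schema or IngestSchema()
    df = pd.read_csv(path, dtype=str, keep_default_na=True, comment="#")
    for col in (schema.site, schema.date):
        if col not in df.columns:
            raise ConfigurationError(f"missing required column {col!r} in {path}")
    if schema.long_format:
        return _read_long(df, schema)
    return _read_wide(df, schema)


def _read_wide(df: pd.DataFrame, schema: IngestSchema) -> IngestResult:
    records: list[SampleRecord] = []
    rejects: list[tuple[int, str]] = []
    present = {a: c for a, c in schema.analytes.items() if c in df.columns}
    for idx, row in df.iterrows():
        try:
            ts = pd.Timestamp(row[schema.date]).normalize()
        except (ValueError, TypeError):
            rejects.append((idx, "bad_date"))
            continue
        q = None
        if schema.discharge and schema.discharge in df.columns:
            raw_q = row[schema.discharge]
            if isinstance(raw_q, str) and raw_q.strip():
                q = float(raw_q)
            if q is not None and q < 0:
                rejects.append((idx, "negative_discharge"))
                continue
        conc: dict[str, QualifiedValue] = {}
        bad = None
        for analyte, col in present.items():
            hint_col = col + schema.qualifier_suffix
            hint = row[hint_col] if hint_col in df.columns else None
            if isinstance(hint, float) and np.isnan(hint):
                hint = None
            try:
                qv = _parse_cell(row[col], hint, schema.units.get(analyte))
            except ValueError as exc:
                bad = "negative" if "negative" in str(exc) else "unparseable"
                break
            if qv is not None:
                conc[analyte] = qv
        if bad:
            rejects.append((idx, bad))
            continue
        records.append(SampleRecord(str(row[schema.site]), ts, q, conc))
    return IngestResult(records, pd.DataFrame(rejects, columns=["row", "reason"]))


def _read_long(df: pd.DataFrame, schema: IngestSchema) -> IngestResult:
    for col in (schema.analyte_col, schema.value_col):
        if col not in df.columns:
            raise ConfigurationError(f"missing required column {col!r}")
    by_key: dict[tuple, SampleRecord] = {}
    rejects: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        analyte = str(row[schema.analyte_col]).strip()
        if analyte not in ANALYTES:
            rejects.append((idx, "unknown_analyte"))
            continue
        try:
            ts = pd.Timestamp(row[schema.date]).normalize()
        except (ValueError, TypeError):
            rejects.append((idx, "bad_date"))
            continue
        hint = row[schema.qualifier_col] if schema.qualifier_col in df.columns else None
        unit = row[schema.unit_col] if schema.unit_col and schema.unit_col in df.columns else None
        try:
            qv = _parse_cell(row[schema.value_col], hint, unit)
        except ValueError as exc:
            rejects.append((idx, "negative" if "negative" in str(exc) else "unparseable"))
            continue
        if qv is None:
            continue
        key = (str(row[schema.site]), ts)
        rec = by_key.setdefault(key, SampleRecord(key[0], key[1]))
        if schema.discharge and schema.discharge in df.columns:
            raw_q = row[schema.discharge]
            if isinstance(raw_q, str) and raw_q.strip():
                rec.discharge_q = float(raw_q)
        rec.conc[analyte] = qv
    return IngestResult(list(by_key.values()), pd.DataFrame(rejects, columns=["row", "reason"]))


def records_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Wide DataFrame view of SampleRecords (one row per record)."""
    rows = []
    for rec in records:
        row: dict = {
            "site_id": rec.site_id,
            "date": pd.Timestamp(rec.timestamp),
            "discharge_lps": np.nan if rec.discharge_q is None else float(rec.discharge_q),
        }
        for analyte, qv in rec.conc.items():
            row[analyte] = qv.value
            row[analyte + QUAL_SUFFIX] = qv.qualifier.value
        rows.append(row)
    cols = ["site_id", "date", "discharge_lps"]
    for a in ANALYTES:
        cols += [a, a + QUAL_SUFFIX]
    frame = pd.DataFrame(rows)
    for c in cols:
        if c not in frame.columns:
            frame[c] = np.nan if not c.endswith(QUAL_SUFFIX) else pd.NA
    return frame[cols]


def frame_to_records(frame: pd.DataFrame) -> list[SampleRecord]:
    records = []
    for _, row in frame.iterrows():
        conc = {}
        for a in ANALYTES:
            if a in frame.columns and pd.notna(row[a]):
                qual = row.get(a + QUAL_SUFFIX)
                qual = Qualifier(qual) if isinstance(qual, str) else Qualifier.measured
                conc[a] = QualifiedValue(float(row[a]), qual)
        q = row.get("discharge_lps")
        records.append(
            SampleRecord(
                str(row["site_id"]),
                pd.Timestamp(row["date"]),
                None if pd.isna(q) else float(q),
                conc,
            )
        )
    return records


# NLCD-style land-use class columns and their aggregation targets.
_LANDUSE_CLASSES = {
    "p_cro": ("pct_crop",),
    "p_hay": ("pct_hay",),
    "p_urb": ("pct_urban_low", "pct_urban_medium", "pct_urban_high"),
    "p_for": ("pct_forest_deciduous", "pct_forest_mixed", "pct_forest_coniferous"),
}


def read_landuse_table(path_or_frame) -> dict[str, LandUseProfile]:
    """Read per-site land-use percentages and aggregate to proportions.

    Urban = low + medium + high intensity; forest = deciduous + mixed +
    coniferous; crop and pasture (hay) are kept separate.  Percentages are
    divided by 100; a class sum above 100.5 raises ValueError.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame
    else:
        df = pd.read_csv(path_or_frame, comment="#")
    if "site_id" not in df.columns:
        raise ConfigurationError("missing required column 'site_id'")
    profiles: dict[str, LandUseProfile] = {}
    for _, row in df.iterrows():
        agg = {}
        for target, cols in _LANDUSE_CLASSES.items():
            agg[target] = float(sum(float(row[c]) for c in cols if c in df.columns))
        total_pct = sum(agg.values())
        if total_pct > 100.5:
            raise ValueError(
                f"site {row['site_id']}: land-use classes sum to {total_pct:.1f}% > 100.5%"
            )
        props = {k: v / 100.0 for k, v in agg.items()}
        p_other = max(0.0, 1.0 - sum(props.values()))
        area = float(row["watershed_area_km2"]) if "watershed_area_km2" in df.columns else np.nan
        profiles[str(row["site_id"])] = LandUseProfile(
            str(row["site_id"]), props["p_cro"], props["p_hay"], props["p_urb"],
            props["p_for"], p_other, area,
        )
    return profiles


def landuse_to_frame(profiles: Mapping[str, LandUseProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_id": p.site_id,
                "p_cro": p.p_cro,
                "p_hay": p.p_hay,
                "p_urb": p.p_urb,
                "p_for": p.p_for,
                "p_other": p.p_other,
                "watershed_area_km2": p.watershed_area_km2,
            }
            for p in profiles.values()
        ]
    )


@dataclass
class JoinResult:
    frame: pd.DataFrame
    n_orphans: int
    orphan_sites: list[str]


def join_site_data(samples, landuse) -> JoinResult:
    """Inner-join samples with land-use profiles on site_id.

    Samples at unprofiled sites are counted as orphans (reported, dropped).
    Output is sorted chronologically within site.  An empty intersection is a
    hard error with site-id diagnostics.
    """
    frame = samples if isinstance(samples, pd.DataFrame) else records_to_frame(samples)
    lu = landuse if isinstance(landuse, pd.DataFrame) else landuse_to_frame(landuse)
    joined = frame.merge(lu, on="site_id", how="inner")
    orphan_mask = ~frame["site_id"].isin(set(lu["site_id"]))
    orphan_sites = sorted(frame.loc[orphan_mask, "site_id"].unique())
    if len(joined) == 0 and len(frame) > 0:
        raise ValueError(
            "no samples matched a land-use profile; sample sites e.g. "
            f"{sorted(frame['site_id'].unique())[:5]} vs. profiled sites e.g. "
            f"{sorted(lu['site_id'].unique())[:5]}"
        )
    if orphan_mask.any():
        warnings.warn(f"{int(orphan_mask.sum())} samples at unprofiled sites dropped")
    joined = joined.sort_values(["site_id", "date"], kind="mergesort").reset_index(drop=True)
    return JoinResult(joined, int(orphan_mask.sum()), list(orphan_sites))
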