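"""Monte-Carlo ascription of uncertainty to qualified concentration values.

"Estimated" concentrations are replaced by a draw from a normal centred on
the reported value (sd = cv x value, truncated at zero by resampling, so
there is no point mass at zero); "less-than" values are replaced by a draw
from a uniform between a configurable floor (default 0) and the reporting
limit.  Measured values pass through untouched.  This avoids discarding or
half-limit-substituting left-censored data.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .ingest import ANALYTES, QUAL_SUFFIX, QualifiedValue, Qualifier

__all__ = ["CensoringPolicy", "impute_qualified_value", "impute_table"]


@dataclass(frozen=True)
class CensoringPolicy:
    """Distributional choices for qualified values.

    cv_estimated : coefficient of variation of the normal used for
        "estimated" values (unitless; 0.10 default, a typical analytical
        relative error).
    lower_bound_lt : floor of the uniform used for "less-than" values
        (mg/L; default 0 = agnostic below the reporting limit).
    seed : default stream seed when none is passed to :func:`impute_table`.
    """

    cv_estimated: float = 0.10
    lower_bound_lt: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.cv_estimated < 0:
            raise ValueError("cv_estimated must be >= 0")
        if self.lower_bound_lt < 0:
            raise ValueError("lower_bound_lt must be >= 0")


def impute_qualified_value(
    qv: QualifiedValue, policy: CensoringPolicy, rng: np.random.Generator
) -> float:
    """One Monte-Carlo draw for a qualified value; always >= 0."""
    if qv.qualifier is Qualifier.measured:
        return qv.value
    if qv.qualifier is Qualifier.estimated:
        sd = policy.cv_estimated * qv.value
        if sd == 0.0:
            return qv.value
        draw = rng.normal(qv.value, sd)
        while draw < 0.0:  # truncate by resampling, not clipping
            draw = rng.normal(qv.value, sd)
        return float(draw)
    # less_than: value is the reporting limit
    limit = qv.value
    lo = policy.lower_bound_lt
    if lo > limit:
        raise ValueError(f"lower_bound_lt={lo} exceeds reporting limit {limit}")
    if lo == limit:
        return limit
    return float(rng.uniform(lo, limit))


def impute_table(
    frame: pd.DataFrame,
    policy: CensoringPolicy,
    seed: int | None = None,
    realization: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace every qualified concentration in the table with one draw.

    Each qualified cell gets its own substream keyed on (seed, site, date,
    analyte, realization) so records are independent but reproducible.
    Returns the imputed table and a log of imputation counts by analyte and
    qualifier.
    """
    seed = policy.seed if seed is None else seed
    out = frame.copy()
    log_rows: list[dict] = []
    for ai, analyte in enumerate(ANALYTES):
        qcol = analyte + QUAL_SUFFIX
        if analyte not in frame.columns or qcol not in frame.columns:
            continue
        quals = frame[qcol]
        counts = {"estimated": 0, "less_than": 0}
        flagged = quals.isin(list(counts))
        if not flagged.any():
            continue
        for idx in frame.index[flagged]:
            qv = QualifiedValue(float(frame.at[idx, analyte]), Qualifier(quals.at[idx]))
            rng = substream(
                seed, "censoring", frame.at[idx, "site_id"], frame.at[idx, "date"],
                ai, realization,
            )
            out.at[idx, analyte] = impute_qualified_value(qv, policy, rng)
            counts[qv.qualifier.value] += 1
        for qualifier, n in counts.items():
            if n:
                log_rows.append({"analyte": analyte, "qualifier": qualifier, "n_imputed": n})
    log = pd.DataFrame(log_rows, columns=["analyte", "qualifier", "n_imputed"])
    return out, log
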