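"""Survey-style descriptive summaries: detection rates, exceedance rates,
ranges and means per element x category (or per material).

Conventions: ranges are reported on the raw data with non-detects shown as 0
(mirroring how censored surveys print zero minima); means and SDs use the
LOD/2-substituted values; exceedance is a strict comparison against the
material-resolved regulatory limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .core_data import (
    ELEMENTS,
    BatchRecord,
    Category,
    Element,
    LimitSet,
    limits_for,
)

__all__ = [
    "CellSummary",
    "detection_rate",
    "exceedance_rate",
    "cell_summary",
    "summary_table",
]


@dataclass(frozen=True)
class CellSummary:
    """Summary of one element within one group of batches."""

    n: int
    range_lo: float
    range_hi: float
    mean: float
    sd: float
    detection_rate: float
    exceedance_rate: float


def detection_rate(records: Sequence[BatchRecord], element: Element) -> float:
    """Fraction of batches in which the element was detected (above LOD)."""
    if not records:
        raise ValueError("detection_rate: empty record collection")
    return sum(r.detected[element] for r in records) / len(records)


def exceedance_rate(
    records: Sequence[BatchRecord],
    element: Element,
    resolve_limits: Callable[[str], LimitSet] = limits_for,
) -> float:
    """Fraction of batches strictly above the material's regulatory limit.

    Records must already be substituted so every concentration is set; the
    limit is resolved per material (species-specific overrides apply).
    """
    if not records:
        raise ValueError("exceedance_rate: empty record collection")
    count = 0
    for r in records:
        c = r.conc[element]
        if math.isnan(c):
            raise ValueError(f"batch {r.batch_id!r} not substituted for {element.value}")
        if c > resolve_limits(r.material)[element]:
            count += 1
    return count / len(records)


def _raw_values(records: Sequence[BatchRecord], element: Element) -> np.ndarray:
    """Raw concentrations with non-detects displayed as 0."""
    return np.array(
        [r.conc[element] if r.detected[element] else 0.0 for r in records]
    )


def cell_summary(
    records: Sequence[BatchRecord],
    element: Element,
    category: Category | None = None,
    resolve_limits: Callable[[str], LimitSet] = limits_for,
    mean_nd: Literal["half_lod", "zero"] = "half_lod",
) -> CellSummary:
    """Summarize one element over one category (or all records).

    ``mean_nd`` selects how non-detects enter the mean/SD: the substituted
    LOD/2 values (default) or zeros.
    """
    group = [r for r in records if category is None or r.category == category]
    if not group:
        raise ValueError(f"cell_summary: no records in cell ({category}, {element})")
    raw = _raw_values(group, element)
    if mean_nd == "half_lod":
        vals = np.array([r.conc[e] for r in group for e in (element,)])
        if np.isnan(vals).any():
            raise ValueError("cell_summary: records not substituted (run substitute_nd)")
    else:
        vals = raw
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return CellSummary(
        n=len(group),
        range_lo=float(raw.min()),
        range_hi=float(raw.max()),
        mean=float(vals.mean()),
        sd=sd,
        detection_rate=detection_rate(group, element),
        exceedance_rate=exceedance_rate(group, element, resolve_limits),
    )


def summary_table(
    records: Sequence[BatchRecord],
    resolve_limits: Callable[[str], LimitSet] = limits_for,
    mean_nd: Literal["half_lod", "zero"] = "half_lod",
) -> pd.DataFrame:
    """Long-format table of cell summaries: overall plus one row per
    (element, category)."""
    rows = []
    groups: list[tuple[str, Category | None]] = [("overall", None)] + [
        (c.value, c) for c in Category
    ]
    for e in ELEMENTS:
        for label, cat in groups:
            s = cell_summary(records, e, cat, resolve_limits, mean_nd)
            rows.append(
                {
                    "element": e.value,
                    "group": label,
                    "n": s.n,
                    "range_lo": s.range_lo,
                    "range_hi": s.range_hi,
                    "mean": s.mean,
                    "sd": s.sd,
                    "detection_rate_pct": 100.0 * s.detection_rate,
                    "exceedance_rate_pct": 100.0 * s.exceedance_rate,
                }
            )
    return pd.DataFrame(rows)
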