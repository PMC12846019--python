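"""Single-factor (P_i) and Nemerow composite (P_N) pollution indices.

P_i = C/S compares a concentration to its regulatory limit; P_N combines the
mean and the maximum of the five per-element indices,

    P_N = sqrt((P_mean^2 + P_max^2) / 2),

so one strongly exceeding element cannot be averaged away. Classification
bands (boundaries belong to the lower class):

    P_i: <=1 non | <=2 slight | <=3 moderate | >3 heavy
    P_N: <=0.7 safe | <=1 alert | <=2 slight | <=3 moderate | >3 heavy
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import pandas as pd

from .core_data import ELEMENTS, BatchRecord, Element, LimitSet, limits_for

__all__ = [
    "PI_CLASSES",
    "PN_CLASSES",
    "PiResult",
    "PnResult",
    "classify_pi",
    "classify_pn",
    "single_factor_index",
    "nemerow_index",
    "batch_pollution",
    "material_pollution",
    "batch_pollution_table",
]

PI_CLASSES = ("non", "slight", "moderate", "heavy")
PN_CLASSES = ("safe", "alert", "slight", "moderate", "heavy")


def classify_pi(value: float) -> str:
    if value < 0:
        raise ValueError("P_i must be >= 0")
    if value <= 1:
        return "non"
    if value <= 2:
        return "slight"
    if value <= 3:
        return "moderate"
    return "heavy"


def classify_pn(value: float) -> str:
    if value < 0:
        raise ValueError("P_N must be >= 0")
    if value <= 0.7:
        return "safe"
    if value <= 1:
        return "alert"
    if value <= 2:
        return "slight"
    if value <= 3:
        return "moderate"
    return "heavy"


@dataclass(frozen=True)
class PiResult:
    element: Element
    value: float
    klass: str


@dataclass(frozen=True)
class PnResult:
    value: float
    klass: str
    pi_vector: tuple[PiResult, ...]


def single_factor_index(C: float, S: float, element: Element) -> PiResult:
    """P_i = C/S with its pollution class."""
    if S <= 0:
        raise ValueError("regulatory limit S must be > 0")
    if C < 0 or math.isnan(C):
        raise ValueError("concentration C must be a non-negative number")
    v = C / S
    return PiResult(element=element, value=v, klass=classify_pi(v))


def nemerow_index(pi: Sequence[PiResult]) -> PnResult:
    """Composite index over exactly the five per-element indices."""
    if len(pi) != len(ELEMENTS):
        raise ValueError(f"nemerow_index expects {len(ELEMENTS)} P_i values, got {len(pi)}")
    values = [p.value for p in pi]
    if any(v < 0 for v in values):
        raise ValueError("P_i values must be >= 0")
    mean = sum(values) / len(values)
    mx = max(values)
    v = math.sqrt((mean**2 + mx**2) / 2.0)
    return PnResult(value=v, klass=classify_pn(v), pi_vector=tuple(pi))


def batch_pollution(
    record: BatchRecord,
    resolve_limits: Callable[[str], LimitSet] = limits_for,
) -> PnResult:
    """Per-element P_i and composite P_N for one substituted batch, under the
    material-resolved limit set."""
    if not record.substituted:
        raise ValueError(f"batch {record.batch_id!r}: substitute non-detects first")
    limits = resolve_limits(record.material)
    pis = [single_factor_index(record.conc[e], limits[e], e) for e in ELEMENTS]
    return nemerow_index(pis)


def material_pollution(
    records: Sequence[BatchRecord],
    resolve_limits: Callable[[str], LimitSet] = limits_for,
    mode: Literal["mean", "max"] = "mean",
) -> PnResult:
    """Material-level indices over all batches of one material.

    mode="mean": P_i from mean substituted concentrations (one representative
    profile per material); mode="max": element-wise worst batch.
    """
    if not records:
        raise ValueError("material_pollution: empty record collection")
    materials = {r.material for r in records}
    if len(materials) != 1:
        raise ValueError(f"material_pollution: mixed materials {sorted(materials)}")
    limits = resolve_limits(records[0].material)
    pis = []
    for e in ELEMENTS:
        values = [r.conc[e] for r in records]
        if any(math.isnan(v) for v in values):
            raise ValueError("material_pollution: substitute non-detects first")
        if mode == "mean":
            c = sum(values) / len(values)
            pis.append(single_factor_index(c, limits[e], e))
        elif mode == "max":
            per_batch = [single_factor_index(v, limits[e], e).value for v in values]
            v = max(per_batch)
            pis.append(PiResult(element=e, value=v, klass=classify_pi(v)))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return nemerow_index(pis)


def batch_pollution_table(
    records: Sequence[BatchRecord],
    resolve_limits: Callable[[str], LimitSet] = limits_for,
) -> pd.DataFrame:
    """Long-format P_i table: one row per (batch, element), plus P_N."""
    rows = []
    for r in records:
        pn = batch_pollution(r, resolve_limits)
        for pi in pn.pi_vector:
            rows.append(
                {
                    "batch_id": r.batch_id,
                    "material": r.material,
                    "category": r.category.value,
                    "element": pi.element.value,
                    "P_i": pi.value,
                    "pi_class": pi.klass,
                    "P_N": pn.value,
                    "pn_class": pn.klass,
                }
            )
    return pd.DataFrame(rows)
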