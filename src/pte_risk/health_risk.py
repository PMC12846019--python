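"""Deterministic dietary health-risk model (USEPA chronic-intake form).

Non-carcinogenic target hazard quotient per element,

    THQ = (EF * ED * IRD * C * t * 1e-3) / (RfD * BW * AT)

with EF days/year, ED years, IRD g/day (1e-3 converts g to kg), C mg/kg dry
weight, t the decoction transfer fraction, RfD mg/(kg*d), BW kg, AT days.
HI is the sum of the five THQs. Lifetime carcinogenic risk for the elements
with a slope factor (As, Pb, Cd),

    CR = (EF * ED * IRD * C * t * CSF * 1e-3) / (BW * AT)

which equals THQ * RfD * CSF. The same 70-year averaging time is used for
both quotients (the model is calibrated for intermittent medicinal intake).
Acceptable CR spans 1e-6 to 1e-4; HI < 1 indicates no expected
non-carcinogenic effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import pandas as pd

from .core_data import (
    CARCINOGENS,
    ELEMENTS,
    BatchRecord,
    DoseRegistry,
    Element,
    ExposureParams,
    ToxicityParams,
    default_exposure,
    default_toxicity,
)

__all__ = [
    "RiskProfile",
    "thq",
    "hazard_index",
    "cancer_risk",
    "hi_label",
    "cr_label",
    "material_risk",
    "risk_table",
]

CR_NEGLIGIBLE = 1e-6
CR_SIGNIFICANT = 1e-4


def thq(
    element: Element,
    C: float,
    IRD: float,
    exposure: ExposureParams,
    toxicity: ToxicityParams,
) -> float:
    """Target hazard quotient for one element (dimensionless)."""
    if element not in ELEMENTS:
        raise ValueError(f"unknown element {element!r}")
    if C < 0 or math.isnan(C):
        raise ValueError("concentration must be a non-negative number")
    if IRD <= 0:
        raise ValueError("IRD must be > 0")
    dose = exposure.EF * exposure.ED * IRD * C * toxicity.transfer[element] * 1e-3
    return dose / (toxicity.rfd[element] * exposure.BW * exposure.AT)


def hazard_index(thq_values: Sequence[float] | Mapping[Element, float]) -> float:
    """HI = sum of the five per-element THQs."""
    if isinstance(thq_values, Mapping):
        values = [thq_values[e] for e in ELEMENTS]
    else:
        values = list(thq_values)
    if len(values) != len(ELEMENTS):
        raise ValueError(f"hazard_index expects {len(ELEMENTS)} THQ values")
    if any(v < 0 for v in values):
        raise ValueError("THQ values must be >= 0")
    return float(sum(values))


def cancer_risk(
    element: Element,
    C: float,
    IRD: float,
    exposure: ExposureParams,
    toxicity: ToxicityParams,
) -> float:
    """Lifetime excess cancer probability for one carcinogenic element.

    Elements without a slope factor raise rather than silently return 0.
    """
    if element not in toxicity.csf:
        raise ValueError(f"no carcinogenic slope factor for {element.value}")
    if C < 0 or math.isnan(C):
        raise ValueError("concentration must be a non-negative number")
    if IRD <= 0:
        raise ValueError("IRD must be > 0")
    dose = exposure.EF * exposure.ED * IRD * C * toxicity.transfer[element] * 1e-3
    return dose * toxicity.csf[element] / (exposure.BW * exposure.AT)


def hi_label(hi: float) -> str:
    return "acceptable" if hi < 1.0 else "potential risk"


def cr_label(cr: float) -> str:
    if cr <= CR_NEGLIGIBLE:
        return "negligible"
    if cr <= CR_SIGNIFICANT:
        return "acceptable"
    return "significant"


@dataclass(frozen=True)
class RiskProfile:
    """Deterministic risk summary for one material."""

    material: str
    thq: Mapping[Element, float]
    hi: float
    cr: Mapping[Element, float]  # only elements with a CSF
    cr_total: float
    hi_band: str
    cr_band: str


def material_risk(
    records: Sequence[BatchRecord],
    doses: DoseRegistry,
    exposure: ExposureParams | None = None,
    toxicity: ToxicityParams | None = None,
    conc_mode: Literal["mean", "max"] = "mean",
) -> RiskProfile:
    """THQ/HI/CR for one material, aggregating batch concentrations by
    ``conc_mode`` (mean for a representative profile, max for conservative
    screening)."""
    if not records:
        raise ValueError("material_risk: empty record collection")
    materials = {r.material for r in records}
    if len(materials) != 1:
        raise ValueError(f"material_risk: mixed materials {sorted(materials)}")
    material = records[0].material
    exposure = exposure or default_exposure()
    toxicity = toxicity or default_toxicity()
    ird = doses.for_material(material)

    conc: dict[Element, float] = {}
    for e in ELEMENTS:
        values = [r.conc[e] for r in records]
        if any(math.isnan(v) for v in values):
            raise ValueError("material_risk: substitute non-detects first")
        conc[e] = max(values) if conc_mode == "max" else sum(values) / len(values)

    thqs = {e: thq(e, conc[e], ird, exposure, toxicity) for e in ELEMENTS}
    hi = hazard_index(thqs)
    crs = {e: cancer_risk(e, conc[e], ird, exposure, toxicity) for e in CARCINOGENS}
    cr_total = float(sum(crs.values()))
    return RiskProfile(
        material=material,
        thq=thqs,
        hi=hi,
        cr=crs,
        cr_total=cr_total,
        hi_band=hi_label(hi),
        cr_band=cr_label(cr_total),
    )


def risk_table(
    records: Sequence[BatchRecord],
    doses: DoseRegistry,
    exposure: ExposureParams | None = None,
    toxicity: ToxicityParams | None = None,
    conc_mode: Literal["mean", "max"] = "mean",
) -> pd.DataFrame:
    """One risk row per material present in ``records``."""
    by_material: dict[str, list[BatchRecord]] = {}
    for r in records:
        by_material.setdefault(r.material, []).append(r)
    rows = []
    for material in sorted(by_material):
        p = material_risk(by_material[material], doses, exposure, toxicity, conc_mode)
        row: dict[str, object] = {
            "material": p.material,
            "category": by_material[material][0].category.value,
        }
        for e in ELEMENTS:
            row[f"THQ_{e.value}"] = p.thq[e]
        row["HI"] = p.hi
        for e in CARCINOGENS:
            row[f"CR_{e.value}"] = p.cr[e]
        row["CR_total"] = p.cr_total
        row["hi_band"] = p.hi_band
        row["cr_band"] = p.cr_band
        rows.append(row)
    return pd.DataFrame(rows)
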