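"""Domain types, parameter registries, batch-table I/O and below-LOD handling.

Concentrations are mg/kg dry weight throughout; daily doses (IRD) are g/day,
so the 1e-3 factor in the exposure equations is the g->kg conversion.

Analytical results below the limit of detection (LOD) are "not detected":
on disk they carry an explicit marker (default ``"ND"``), in memory an
explicit boolean flag plus an unset (NaN) concentration. ``substitute_nd``
imputes LOD/2, the standard simple substitution for left-censored
environmental data, after which every concentration is strictly positive.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "Element",
    "ELEMENTS",
    "Category",
    "BatchRecord",
    "LimitSet",
    "LimitRegistry",
    "LodSet",
    "ExposureParams",
    "ToxicityParams",
    "DoseRegistry",
    "load_defaults",
    "default_limit_registry",
    "default_lods",
    "default_exposure",
    "default_toxicity",
    "limits_for",
    "read_batches",
    "write_batches",
    "substitute_nd",
]


class Element(str, Enum):
    """The five potentially toxic elements assessed."""

    As = "As"
    Hg = "Hg"
    Pb = "Pb"
    Cd = "Cd"
    Cu = "Cu"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


ELEMENTS: tuple[Element, ...] = tuple(Element)

#: Elements with an established oral carcinogenic slope factor.
CARCINOGENS: tuple[Element, ...] = (Element.As, Element.Pb, Element.Cd)


class Category(str, Enum):
    """Medicinal-material category (by raw material and medicinal part)."""

    ROOTS_RHIZOMES = "roots_rhizomes"  # underground parts
    ABOVEGROUND = "aboveground"  # stems/leaves, whole herbs, flowers, fruits, seeds
    ANIMAL = "animal"  # animal-derived decoction pieces

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _norm_name(material: str) -> str:
    """Whitespace-normalized, case-insensitive key for material lookup."""
    return re.sub(r"\s+", " ", material.strip()).casefold()


@dataclass
class BatchRecord:
    """One analyzed batch: five concentrations plus censoring flags.

    ``conc[e]`` is NaN while ``detected[e]`` is False and the record has not
    been through :func:`substitute_nd`.
    """

    batch_id: str
    material: str
    category: Category
    conc: dict[Element, float]
    detected: dict[Element, bool]

    def __post_init__(self) -> None:
        for e in ELEMENTS:
            if e not in self.conc or e not in self.detected:
                raise ValueError(f"batch {self.batch_id!r}: missing element {e.value}")
            c = self.conc[e]
            if not math.isnan(c) and c < 0:
                raise ValueError(
                    f"batch {self.batch_id!r}: negative concentration {c} for {e.value}"
                )

    @property
    def substituted(self) -> bool:
        """True once every concentration (incl. non-detects) is set."""
        return all(not math.isnan(self.conc[e]) for e in ELEMENTS)


@dataclass(frozen=True)
class LimitSet:
    """Per-element regulatory limits, mg/kg."""

    values: Mapping[Element, float]

    def __post_init__(self) -> None:
        for e in ELEMENTS:
            if e not in self.values:
                raise ValueError(f"limit missing for {e.value}")
            if self.values[e] <= 0:
                raise ValueError(f"limit for {e.value} must be > 0")

    def __getitem__(self, e: Element) -> float:
        return self.values[e]


@dataclass(frozen=True)
class LodSet:
    """Per-element limits of detection, mg/kg."""

    values: Mapping[Element, float]

    def __post_init__(self) -> None:
        for e in ELEMENTS:
            if e not in self.values or self.values[e] <= 0:
                raise ValueError(f"LOD for {e.value} must be present and > 0")

    def __getitem__(self, e: Element) -> float:
        return self.values[e]


@dataclass(frozen=True)
class LimitRegistry:
    """Default limit set plus per-material overrides (e.g. animal species
    with their own pharmacopoeia limits)."""

    default: LimitSet
    overrides: Mapping[str, LimitSet] = field(default_factory=dict)

    def limits_for(self, material: str) -> LimitSet:
        """Resolve the limit set for a material (exact match, case- and
        whitespace-insensitive); unknown materials get the default set."""
        key = _norm_name(material)
        for name, lim in self.overrides.items():
            if _norm_name(name) == key:
                return lim
        return self.default


@dataclass(frozen=True)
class ExposureParams:
    """Population exposure parameters for the chronic-intake model.

    EF: exposure frequency, days/year. ED: exposure duration, years.
    BW: adult body weight, kg. AT: averaging time, days (70 y lifetime).
    """

    EF: float = 90.0
    ED: float = 20.0
    BW: float = 60.0
    AT: float = 365.0 * 70.0

    def __post_init__(self) -> None:
        for name in ("EF", "ED", "BW", "AT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class ToxicityParams:
    """Per-element toxicity constants.

    transfer: fraction of the element passing into the water decoction.
    rfd: oral reference dose, mg/(kg*d).
    csf: carcinogenic slope factor, (mg/(kg*d))^-1, only for As/Pb/Cd.
    """

    transfer: Mapping[Element, float]
    rfd: Mapping[Element, float]
    csf: Mapping[Element, float]

    def __post_init__(self) -> None:
        for e in ELEMENTS:
            t = self.transfer.get(e)
            if t is None or not (0 < t <= 1):
                raise ValueError(f"transfer rate for {e.value} must be in (0, 1]")
            if self.rfd.get(e, 0) <= 0:
                raise ValueError(f"RfD for {e.value} must be present and > 0")
        for e, v in self.csf.items():
            if v <= 0:
                raise ValueError(f"CSF for {Element(e).value} must be > 0")


@dataclass(frozen=True)
class DoseRegistry:
    """Material -> daily consumption (IRD), g/day."""

    doses: Mapping[str, float]

    def for_material(self, material: str) -> float:
        key = _norm_name(material)
        for name, d in self.doses.items():
            if _norm_name(name) == key:
                if d <= 0:
                    raise ValueError(f"dose for {material!r} must be > 0")
                return d
        raise KeyError(f"no daily dose registered for material {material!r}")


# ---------------------------------------------------------------------------
# packaged defaults


def _elem_map(d: Mapping[str, float]) -> dict[Element, float]:
    return {Element(k): float(v) for k, v in d.items()}


def load_defaults(path: str | Path | None = None) -> dict:
    """Load the parameter registry file (packaged defaults unless ``path``)."""
    if path is None:
        text = resources.files("pte_risk.data").joinpath("defaults.yaml").read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def default_limit_registry(path: str | Path | None = None) -> LimitRegistry:
    raw = load_defaults(path)["limits"]
    return LimitRegistry(
        default=LimitSet(_elem_map(raw["default"])),
        overrides={m: LimitSet(_elem_map(v)) for m, v in raw.get("overrides", {}).items()},
    )


def default_lods(path: str | Path | None = None) -> LodSet:
    return LodSet(_elem_map(load_defaults(path)["lod"]))


def default_exposure(path: str | Path | None = None) -> ExposureParams:
    raw = load_defaults(path)["exposure"]
    return ExposureParams(**{k: float(v) for k, v in raw.items()})


def default_toxicity(path: str | Path | None = None) -> ToxicityParams:
    raw = load_defaults(path)["toxicity"]
    return ToxicityParams(
        transfer=_elem_map(raw["transfer"]),
        rfd=_elem_map(raw["rfd"]),
        csf=_elem_map(raw["csf"]),
    )


_DEFAULT_REGISTRY = default_limit_registry()


def limits_for(material: str) -> LimitSet:
    """Limit set for a material under the packaged default registry."""
    return _DEFAULT_REGISTRY.limits_for(material)


# ---------------------------------------------------------------------------
# batch-table I/O

_REQUIRED = ["batch_id", "material", "category"]


def read_batches(path: str | Path, nd_marker: str = "ND") -> list[BatchRecord]:
    """Read a batch concentration table (CSV with header).

    Columns: ``batch_id, material, category, As, Hg, Pb, Cd, Cu``. Cells equal
    to ``nd_marker`` become non-detects; numeric cells are mg/kg.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _REQUIRED + [e.value for e in ELEMENTS]:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    records: list[BatchRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        raw = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            category = Category(raw["category"].strip())
        except ValueError:
            raise ValueError(
                f"{path}: row {i}: unknown category {raw['category']!r}"
            ) from None
        conc: dict[Element, float] = {}
        detected: dict[Element, bool] = {}
        for e in ELEMENTS:
            cell = raw[e.value].strip()
            if cell == nd_marker:
                conc[e] = math.nan
                detected[e] = False
            else:
                try:
                    value = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: row {i}: non-numeric {e.value} cell {cell!r}"
                    ) from None
                if value < 0:
                    raise ValueError(
                        f"{path}: row {i}: negative concentration {value} for {e.value}"
                    )
                conc[e] = value
                detected[e] = True
        records.append(
            BatchRecord(
                batch_id=raw["batch_id"],
                material=raw["material"],
                category=category,
                conc=conc,
                detected=detected,
            )
        )
    return records


def write_batches(
    records: Iterable[BatchRecord], path: str | Path, nd_marker: str = "ND"
) -> None:
    """Write records as CSV; non-detected cells are re-emitted as the marker
    so the censoring information round-trips."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "batch_id": r.batch_id,
            "material": r.material,
            "category": r.category.value,
        }
        for e in ELEMENTS:
            row[e.value] = nd_marker if not r.detected[e] else repr(r.conc[e])
        rows.append(row)
    pd.DataFrame(rows, columns=_REQUIRED + [e.value for e in ELEMENTS]).to_csv(
        path, index=False
    )


def substitute_nd(
    records: Sequence[BatchRecord], lods: LodSet | None = None
) -> list[BatchRecord]:
    """Impute LOD/2 for every non-detected concentration (idempotent).

    Detected values are untouched; the censoring flags are preserved so
    descriptive statistics can still distinguish the two populations.
    """
    if lods is None:
        lods = default_lods()
    out = []
    for r in records:
        conc = {
            e: (r.conc[e] if r.detected[e] else lods[e] / 2.0) for e in ELEMENTS
        }
        out.append(replace(r, conc=conc, detected=dict(r.detected)))
    return out
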