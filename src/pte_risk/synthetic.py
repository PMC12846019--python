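"""Synthetic batch-concentration tables with realistic censored structure.

The generator emulates a survey of medicinal-material batches: three material
categories x five elements, each cell modelled as a Bernoulli detection mask
over a truncated lognormal for the detected concentrations, plus optional
rare "hotspot" batches carrying extreme values (a single lognormal cannot
produce both the observed cell means and maxima of tens of mg/kg).

The packaged default spec is calibrated so that, in expectation, each cell
reproduces a target detection rate and a target mean/SD of the substituted
concentration distribution; calibration is analytic (moment matching) with a
one-dimensional root solve for the log-location when the cell is truncated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.stats import norm

from .core_data import ELEMENTS, BatchRecord, Category, DoseRegistry, Element

__all__ = [
    "CellSpec",
    "CellTarget",
    "GeneratorSpec",
    "DEFAULT_CELL_TARGETS",
    "calibrate_cell",
    "default_spec",
    "generate_batches",
    "dose_registry",
]


@dataclass(frozen=True)
class CellSpec:
    """Sampling law for one (category, element) cell.

    mu_log/sigma_log parameterize the lognormal of detected draws; detect_p
    is the Bernoulli detection probability; max_cap truncates the lognormal
    (upper bound, mg/kg); hotspots is a list of (probability, value) extreme
    injections that override the lognormal draw.
    """

    mu_log: float
    sigma_log: float
    detect_p: float
    max_cap: float | None = None
    hotspots: tuple[tuple[float, float], ...] = ()

    def validate(self) -> None:
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")
        if not (0.0 <= self.detect_p <= 1.0):
            raise ValueError("detect_p must lie in [0, 1]")
        if self.max_cap is not None and self.max_cap <= 0:
            raise ValueError("max_cap must be > 0")
        q = sum(p for p, _ in self.hotspots)
        if any(p < 0 or v < 0 for p, v in self.hotspots) or q > 1:
            raise ValueError("hotspot probabilities must be >= 0 and sum <= 1")


@dataclass(frozen=True)
class GeneratorSpec:
    """Complete recipe for one synthetic survey."""

    cells: Mapping[tuple[Category, Element], CellSpec]
    n_batches: Mapping[Category, int]
    materials: Mapping[Category, tuple[tuple[str, float], ...]]  # (name, IRD g/day)
    seed: int = 0

    def validate(self) -> None:
        for cat in Category:
            for e in ELEMENTS:
                if (cat, e) not in self.cells:
                    raise ValueError(f"missing cell spec for ({cat.value}, {e.value})")
            if self.n_batches.get(cat, 0) < 1:
                raise ValueError(f"n_batches for {cat.value} must be >= 1")
            if not self.materials.get(cat):
                raise ValueError(f"empty material pool for {cat.value}")
        for key, cell in self.cells.items():
            try:
                cell.validate()
            except ValueError as err:
                raise ValueError(f"cell {key}: {err}") from None

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "seed": self.seed,
            "n_batches": {c.value: int(self.n_batches[c]) for c in Category},
            "materials": {
                c.value: [[m, float(d)] for m, d in self.materials[c]] for c in Category
            },
            "cells": {
                f"{c.value}/{e.value}": {
                    "mu_log": float(s.mu_log),
                    "sigma_log": float(s.sigma_log),
                    "detect_p": float(s.detect_p),
                    "max_cap": None if s.max_cap is None else float(s.max_cap),
                    "hotspots": [[float(p), float(v)] for p, v in s.hotspots],
                }
                for (c, e), s in self.cells.items()
            },
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorSpec":
        doc = yaml.safe_load(Path(path).read_text())
        cells = {}
        for key, s in doc["cells"].items():
            cat_s, elem_s = key.split("/")
            cells[(Category(cat_s), Element(elem_s))] = CellSpec(
                mu_log=s["mu_log"],
                sigma_log=s["sigma_log"],
                detect_p=s["detect_p"],
                max_cap=s.get("max_cap"),
                hotspots=tuple((p, v) for p, v in s.get("hotspots", [])),
            )
        spec = cls(
            cells=cells,
            n_batches={Category(c): int(n) for c, n in doc["n_batches"].items()},
            materials={
                Category(c): tuple((m, float(d)) for m, d in pool)
                for c, pool in doc["materials"].items()
            },
            seed=int(doc.get("seed", 0)),
        )
        spec.validate()
        return spec


# ---------------------------------------------------------------------------
# calibration targets for the packaged default spec


@dataclass(frozen=True)
class CellTarget:
    """Target summary statistics for one cell of the default emulation:
    mean/SD of the (substituted) concentrations, detection rate, and the
    observed concentration range the cell is truncated to."""

    mean: float
    sd: float
    detect_p: float
    lo: float
    hi: float


_R, _A, _N = Category.ROOTS_RHIZOMES, Category.ABOVEGROUND, Category.ANIMAL

#: Published per-cell summaries the default generator is calibrated against.
DEFAULT_CELL_TARGETS: dict[tuple[Category, Element], CellTarget] = {
    (_R, Element.As): CellTarget(0.37, 0.77, 0.842, 0.0, 7.09),
    (_R, Element.Hg): CellTarget(0.03, 0.05, 0.576, 0.0, 0.29),
    (_R, Element.Pb): CellTarget(0.33, 0.71, 0.559, 0.0, 4.10),
    (_R, Element.Cd): CellTarget(0.08, 0.16, 0.559, 0.0, 1.10),
    (_R, Element.Cu): CellTarget(7.06, 5.86, 0.848, 0.0, 49.20),
    (_A, Element.As): CellTarget(0.21, 0.31, 0.735, 0.0, 1.54),
    (_A, Element.Hg): CellTarget(0.07, 0.14, 0.765, 0.0, 1.02),
    (_A, Element.Pb): CellTarget(0.33, 1.13, 0.582, 0.0, 13.0),
    (_A, Element.Cd): CellTarget(0.06, 0.15, 0.565, 0.0, 0.96),
    (_A, Element.Cu): CellTarget(8.72, 6.49, 0.924, 0.0, 43.4),
    (_N, Element.As): CellTarget(3.03, 4.35, 1.000, 0.07, 27.18),
    (_N, Element.Hg): CellTarget(0.15, 0.22, 0.960, 0.0, 1.00),
    (_N, Element.Pb): CellTarget(4.45, 9.03, 0.933, 0.0, 55.0),
    (_N, Element.Cd): CellTarget(0.38, 0.74, 0.947, 0.0, 4.11),
    (_N, Element.Cu): CellTarget(14.1, 9.04, 1.000, 0.23, 43.9),
}

#: Default survey size: batches per category.
DEFAULT_N_BATCHES: dict[Category, int] = {_R: 177, _A: 170, _N: 75}

#: Rare extreme-value injections: (category, element) -> ((prob, value), ...).
_DEFAULT_HOTSPOTS: dict[tuple[Category, Element], tuple[tuple[float, float], ...]] = {
    (_N, Element.As): ((0.004, 27.18),),
    (_N, Element.Pb): ((0.004, 55.0),),
}

_ROOT_MATERIALS = (
    "Notoginseng Radix et Rhizoma", "Ginseng Radix et Rhizoma Rubra",
    "Hedysari Radix", "Polygonati Rhizoma", "Glycyrrhizae Radix et Rhizoma",
    "Astragali Radix", "Angelicae Sinensis Radix",
    "Salviae Miltiorrhizae Radix et Rhizoma", "Paeoniae Radix Alba",
    "Rehmanniae Radix", "Chuanxiong Rhizoma", "Coptidis Rhizoma",
    "Zingiberis Rhizoma", "Atractylodis Macrocephalae Rhizoma",
    "Scutellariae Radix", "Bupleuri Radix", "Platycodonis Radix",
    "Puerariae Lobatae Radix", "Ophiopogonis Radix",
    "Achyranthis Bidentatae Radix", "Codonopsis Radix", "Polygalae Radix",
    "Anemarrhenae Rhizoma", "Alismatis Rhizoma",
)
_ABOVEGROUND_MATERIALS = (
    "Artemisiae Argyi Folium", "Platycladi Cacumen", "Isatidis Folium",
    "Ginkgo Folium", "Dendrobii Caulis", "Magnoliae Flos",
    "Eriobotryae Folium", "Taraxaci Herba", "Menthae Haplocalycis Herba",
    "Ephedrae Herba", "Houttuyniae Herba", "Leonuri Herba",
    "Lonicerae Japonicae Flos", "Chrysanthemi Flos", "Carthami Flos",
    "Lycii Fructus", "Crataegi Fructus", "Gardeniae Fructus",
    "Schisandrae Chinensis Fructus", "Foeniculi Fructus",
    "Citri Reticulatae Pericarpium", "Perillae Folium", "Mori Folium",
    "Nelumbinis Folium", "Armeniacae Semen Amarum", "Coicis Semen",
    "Cassiae Semen", "Ziziphi Spinosae Semen",
)
_ANIMAL_MATERIALS = (
    "Pheretima", "Bombyx Batryticatus", "Cicadae Periostracum",
    "Eupolyphaga Steleophaga", "Aspongopus", "Hirudo", "Sepiae Endoconcha",
)


def _placeholder_dose(index: int) -> float:
    """Deterministic placeholder daily dose in 3-15 g/day."""
    return round(3.0 + 12.0 * ((index * 7) % 25) / 24.0, 1)


def _material_pool(names: Sequence[str]) -> tuple[tuple[str, float], ...]:
    return tuple((name, _placeholder_dose(i)) for i, name in enumerate(names))


# ---------------------------------------------------------------------------
# moment-matched calibration


def _trunc_lognorm_mean(mu: float, sigma: float, cap: float | None) -> float:
    """Mean of a lognormal(mu, sigma) truncated to (0, cap]."""
    m = math.exp(mu + sigma**2 / 2.0)
    if cap is None or sigma == 0.0:
        return min(m, cap) if (cap is not None and sigma == 0.0) else m
    a = (math.log(cap) - mu) / sigma
    return m * norm.cdf(a - sigma) / norm.cdf(a)


def calibrate_cell(target: CellTarget, hotspots: tuple[tuple[float, float], ...] = ()) -> CellSpec:
    """Solve CellSpec parameters so the cell's expected detection rate, mean
    and (approximately) SD match ``target``.

    The detected-part moments are recovered from the whole-cell mean/SD via
    the Bernoulli mixture (non-detects contribute ~0 mass); the lognormal
    shape comes from moment matching on the detected part, and the
    log-location is then solved numerically so that truncation at the
    observed maximum and the hotspot mixture leave the mean unchanged.
    """
    p = target.detect_p
    if p <= 0:
        return CellSpec(mu_log=0.0, sigma_log=0.0, detect_p=0.0, max_cap=target.hi)
    m_x = target.mean / p  # mean of detected draws
    var_x = (target.sd**2 + target.mean**2) / p - m_x**2
    if var_x <= 0:
        sigma = 0.05
    else:
        sigma = math.sqrt(math.log(1.0 + var_x / m_x**2))
    q = sum(pr for pr, _ in hotspots)
    hot_mean = sum(pr * v for pr, v in hotspots)
    body_mean = (m_x - hot_mean) / (1.0 - q)  # required truncated-lognormal mean
    if body_mean <= 0:
        raise ValueError("hotspot mass exceeds the target cell mean")
    cap = target.hi
    if cap is not None and body_mean >= cap:
        raise ValueError("target mean incompatible with truncation cap")

    def gap(mu: float) -> float:
        return _trunc_lognorm_mean(mu, sigma, cap) - body_mean

    naive = math.log(body_mean) - sigma**2 / 2.0
    lo, hi = naive - 1.0, naive + 10.0
    # the truncated mean is increasing in mu and bounded by cap
    while gap(hi) < 0 and hi < naive + 60.0:
        hi += 10.0
    mu = brentq(gap, lo, hi, xtol=1e-12) if gap(lo) < 0 else lo
    return CellSpec(mu_log=mu, sigma_log=sigma, detect_p=p, max_cap=cap, hotspots=hotspots)


def default_spec(seed: int = 0) -> GeneratorSpec:
    """The packaged survey emulation: 177 + 170 + 75 batches over 59
    materials, each cell calibrated to the published summary statistics."""
    cells = {
        key: calibrate_cell(t, _DEFAULT_HOTSPOTS.get(key, ()))
        for key, t in DEFAULT_CELL_TARGETS.items()
    }
    materials = {
        _R: _material_pool(_ROOT_MATERIALS),
        _A: _material_pool(_ABOVEGROUND_MATERIALS),
        _N: _material_pool(_ANIMAL_MATERIALS),
    }
    return GeneratorSpec(
        cells=cells, n_batches=dict(DEFAULT_N_BATCHES), materials=materials, seed=seed
    )


# ---------------------------------------------------------------------------
# sampling


_PREFIX = {_R: "RR", _A: "AG", _N: "AN"}


def _sample_cell(cell: CellSpec, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw n (value, detected) pairs for one cell.

    Truncation uses the inverse-CDF transform, so the draws follow exactly
    the conditional (<= cap) law the calibration assumes.
    """
    det = rng.random(n) < cell.detect_p
    hot_u = rng.random(n)
    base_u = rng.random(n)
    if cell.sigma_log == 0.0:
        x = np.full(n, math.exp(cell.mu_log))
        if cell.max_cap is not None:
            x = np.minimum(x, cell.max_cap)
    else:
        if cell.max_cap is None:
            z = norm.ppf(base_u)
        else:
            a = (math.log(cell.max_cap) - cell.mu_log) / cell.sigma_log
            z = norm.ppf(base_u * norm.cdf(a))
        x = np.exp(cell.mu_log + cell.sigma_log * z)
    acc = 0.0
    for prob, value in cell.hotspots:
        mask = (hot_u >= acc) & (hot_u < acc + prob)
        x[mask] = value
        acc += prob
    x = np.where(det, x, np.nan)
    return x, det


def generate_batches(spec: GeneratorSpec) -> list[BatchRecord]:
    """Sample one full synthetic survey (deterministic given ``spec.seed``).

    Records carry censoring flags, not substituted values; run
    :func:`pte_risk.core_data.substitute_nd` before index/risk computations.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records: list[BatchRecord] = []
    for cat in Category:  # fixed iteration order for determinism
        n = spec.n_batches[cat]
        draws: dict[Element, tuple[np.ndarray, np.ndarray]] = {}
        for e in ELEMENTS:
            draws[e] = _sample_cell(spec.cells[(cat, e)], n, rng)
        pool = spec.materials[cat]
        for i in range(n):
            material = pool[i % len(pool)][0]
            conc = {e: float(draws[e][0][i]) for e in ELEMENTS}
            detected = {e: bool(draws[e][1][i]) for e in ELEMENTS}
            records.append(
                BatchRecord(
                    batch_id=f"{_PREFIX[cat]}{i + 1:04d}",
                    material=material,
                    category=cat,
                    conc=conc,
                    detected=detected,
                )
            )
    return records


def dose_registry(spec: GeneratorSpec) -> DoseRegistry:
    """Daily-dose registry for every material in the spec's pools."""
    doses = {name: d for pool in spec.materials.values() for name, d in pool}
    return DoseRegistry(doses)
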