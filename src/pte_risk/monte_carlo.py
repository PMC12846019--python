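"""Probabilistic risk assessment by Monte-Carlo propagation.

Uncertain inputs (the five element concentrations, daily dose IRD, exposure
frequency EF, body weight BW) are sampled independently per iteration and
propagated through the deterministic THQ/HI/CR model; ED, AT and the
toxicity constants stay fixed. Outputs are the sampled HI and total-CR
distributions, strict exceedance probabilities against the conventional
thresholds (HI > 1, CR > 1e-6, CR > 1e-4), percentiles, and a
contribution-to-variance sensitivity table: each varied input's squared
Spearman rank correlation with the output, normalized to sum to 100% (the
convention used by spreadsheet risk add-ins).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, spearmanr, truncnorm

from .core_data import (
    ELEMENTS,
    BatchRecord,
    Category,
    ExposureParams,
    ToxicityParams,
    default_exposure,
    default_toxicity,
)

__all__ = [
    "DistributionSpec",
    "MCConfig",
    "MCResult",
    "INPUT_KEYS",
    "run_mc",
    "prob_exceed",
    "sensitivity",
    "default_mc_config",
]

#: Canonical sampling order of the varied symbols.
INPUT_KEYS: tuple[str, ...] = ("C_As", "C_Hg", "C_Pb", "C_Cd", "C_Cu", "IRD", "EF", "BW")

_FAMILIES = {"point", "uniform", "triangular", "normal_truncated", "lognormal"}


@dataclass(frozen=True)
class DistributionSpec:
    """One input's sampling law.

    families/params: point {value}; uniform {lo, hi}; triangular
    {lo, mode, hi}; normal_truncated {mean, sd} with bounds; lognormal
    {mu_log, sigma_log} with optional bounds (truncation by inverse CDF).
    """

    family: str
    params: Mapping[str, float]
    bounds: tuple[float, float] | None = None

    def validate(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        p = self.params
        if self.family == "point":
            if "value" not in p:
                raise ValueError("point distribution needs 'value'")
        elif self.family == "uniform":
            if not p.get("lo") < p.get("hi"):  # type: ignore[operator]
                raise ValueError("uniform needs lo < hi")
        elif self.family == "triangular":
            if not (p["lo"] <= p["mode"] <= p["hi"] and p["lo"] < p["hi"]):
                raise ValueError("triangular needs lo <= mode <= hi, lo < hi")
        elif self.family == "normal_truncated":
            if p.get("sd", 0) <= 0:
                raise ValueError("normal_truncated needs sd > 0")
            if self.bounds is None or not self.bounds[0] < self.bounds[1]:
                raise ValueError("normal_truncated needs bounds (lo, hi), lo < hi")
        elif self.family == "lognormal":
            if p.get("sigma_log", -1) < 0:
                raise ValueError("lognormal needs sigma_log >= 0")
        if self.bounds is not None and not self.bounds[0] < self.bounds[1]:
            raise ValueError("bounds must satisfy lo < hi")

    @property
    def is_varied(self) -> bool:
        if self.family == "point":
            return False
        if self.family == "lognormal" and self.params.get("sigma_log") == 0:
            return False
        return True

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "point":
            return np.full(n, float(self.params["value"]))
        if self.family == "uniform":
            return rng.uniform(self.params["lo"], self.params["hi"], n)
        if self.family == "triangular":
            return rng.triangular(self.params["lo"], self.params["mode"], self.params["hi"], n)
        if self.family == "normal_truncated":
            lo, hi = self.bounds  # type: ignore[misc]
            mean, sd = self.params["mean"], self.params["sd"]
            a, b = (lo - mean) / sd, (hi - mean) / sd
            return truncnorm.ppf(rng.random(n), a, b, loc=mean, scale=sd)
        # lognormal
        mu, sigma = self.params["mu_log"], self.params["sigma_log"]
        if sigma == 0:
            return np.full(n, math.exp(mu))
        u = rng.random(n)
        if self.bounds is None:
            z = norm.ppf(u)
        else:
            lo, hi = self.bounds
            alo = norm.cdf((math.log(max(lo, 1e-300)) - mu) / sigma) if lo > 0 else 0.0
            ahi = norm.cdf((math.log(hi) - mu) / sigma)
            z = norm.ppf(alo + u * (ahi - alo))
        return np.exp(mu + sigma * z)


@dataclass(frozen=True)
class MCConfig:
    """Monte-Carlo run configuration: sampled inputs plus fixed parameters."""

    inputs: Mapping[str, DistributionSpec]
    n_iter: int = 10_000
    seed: int = 0
    exposure: ExposureParams = field(default_factory=default_exposure)
    toxicity: ToxicityParams = field(default_factory=default_toxicity)

    def validate(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        for key in INPUT_KEYS:
            if key not in self.inputs:
                raise ValueError(f"missing input distribution for {key!r}")
            try:
                self.inputs[key].validate()
            except ValueError as err:
                raise ValueError(f"input {key!r}: {err}") from None


@dataclass(frozen=True)
class MCResult:
    hi_samples: np.ndarray
    cr_samples: np.ndarray  # total CR over the carcinogenic elements
    p_hi_gt_1: float
    p_cr_gt_1e6: float
    p_cr_gt_1e4: float
    pct: pd.DataFrame  # rows HI / CR_total, columns percentiles
    sensitivity: pd.DataFrame  # rows inputs, columns HI / CR contribution %


def prob_exceed(samples: Sequence[float] | np.ndarray, threshold: float) -> float:
    """Empirical strict-exceedance probability P(X > threshold)."""
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValueError("prob_exceed: empty sample")
    return float(np.mean(arr > threshold))


def sensitivity(
    samples_by_input: Mapping[str, np.ndarray],
    output_samples: np.ndarray,
    varied: Mapping[str, bool] | None = None,
) -> dict[str, float]:
    """Contribution-to-variance table, in percent.

    contribution_j = 100 * rho_j^2 / sum_k rho_k^2 over the varied inputs,
    rho being the Spearman rank correlation with the output; inputs held
    fixed get 0.
    """
    out = np.asarray(output_samples, dtype=float)
    if np.ptp(out) == 0:
        raise ValueError("sensitivity: output is constant; correlations undefined")
    rho2: dict[str, float] = {}
    for key, x in samples_by_input.items():
        is_varied = varied[key] if varied is not None else (np.ptp(np.asarray(x)) > 0)
        if not is_varied:
            rho2[key] = 0.0
            continue
        rho = spearmanr(np.asarray(x, dtype=float), out).statistic
        rho2[key] = 0.0 if math.isnan(rho) else float(rho) ** 2
    total = sum(rho2.values())
    if total == 0:
        raise ValueError("sensitivity: no varied input correlates with the output")
    return {k: 100.0 * v / total for k, v in rho2.items()}


def run_mc(config: MCConfig) -> MCResult:
    """Run the probabilistic assessment (deterministic given config.seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_iter
    draws = {key: config.inputs[key].sample(n, rng) for key in INPUT_KEYS}

    exp, tox = config.exposure, config.toxicity
    EF, BW, IRD = draws["EF"], draws["BW"], draws["IRD"]
    base = exp.ED * 1e-3 / exp.AT  # fixed part of the chronic-dose factor
    hi = np.zeros(n)
    cr = np.zeros(n)
    for e in ELEMENTS:
        C = draws[f"C_{e.value}"]
        dose = EF * IRD * C * tox.transfer[e] * base / BW
        hi += dose / tox.rfd[e]
        if e in tox.csf:
            cr += dose * tox.csf[e]

    varied = {k: config.inputs[k].is_varied for k in INPUT_KEYS}
    q = [5, 25, 50, 75, 95]
    pct = pd.DataFrame(
        {
            f"p{p}": [float(np.percentile(hi, p)), float(np.percentile(cr, p))]
            for p in q
        },
        index=["HI", "CR_total"],
    )
    sens_rows: dict[str, dict[str, float]] = {}
    for label, out in (("HI", hi), ("CR", cr)):
        try:
            sens_rows[label] = sensitivity(draws, out, varied)
        except ValueError:
            sens_rows[label] = {k: float("nan") for k in INPUT_KEYS}
    sens = pd.DataFrame(
        {
            "HI_contribution_pct": [sens_rows["HI"][k] for k in INPUT_KEYS],
            "CR_contribution_pct": [sens_rows["CR"][k] for k in INPUT_KEYS],
        },
        index=list(INPUT_KEYS),
    )
    return MCResult(
        hi_samples=hi,
        cr_samples=cr,
        p_hi_gt_1=prob_exceed(hi, 1.0),
        p_cr_gt_1e6=prob_exceed(cr, 1e-6),
        p_cr_gt_1e4=prob_exceed(cr, 1e-4),
        pct=pct,
        sensitivity=sens,
    )


def default_mc_config(
    records: Sequence[BatchRecord],
    category: Category,
    dose_range: tuple[float, float],
    n_iter: int = 10_000,
    seed: int = 0,
    exposure: ExposureParams | None = None,
    toxicity: ToxicityParams | None = None,
) -> MCConfig:
    """Category-level default configuration.

    Concentrations: lognormal moment-matched to the arithmetic mean/SD of the
    category's substituted concentrations, truncated to the observed range.
    IRD: triangular over the material dose range (mode at the midpoint).
    EF: uniform 30-180 days/year. BW: truncated normal 60 +- 10 kg on 40-100.
    These are modelling assumptions, overridable per input.
    """
    group = [r for r in records if r.category == category]
    if not group:
        raise ValueError(f"no records in category {category.value}")
    inputs: dict[str, DistributionSpec] = {}
    for e in ELEMENTS:
        values = np.array([r.conc[e] for r in group], dtype=float)
        if np.isnan(values).any():
            raise ValueError("default_mc_config: substitute non-detects first")
        mean, sd = float(values.mean()), float(values.std(ddof=1))
        if mean <= 0 or sd == 0:
            inputs[f"C_{e.value}"] = DistributionSpec("point", {"value": mean})
            continue
        cv2 = (sd / mean) ** 2
        sigma = math.sqrt(math.log1p(cv2))
        mu = math.log(mean) - sigma**2 / 2.0
        hi_bound = float(values.max()) * 1.5  # soft cap against unphysical tails
        inputs[f"C_{e.value}"] = DistributionSpec(
            "lognormal", {"mu_log": mu, "sigma_log": sigma}, bounds=(0.0, hi_bound)
        )
    lo, hi = dose_range
    if not 0 < lo <= hi:
        raise ValueError("dose_range must satisfy 0 < lo <= hi")
    if lo == hi:
        inputs["IRD"] = DistributionSpec("point", {"value": lo})
    else:
        inputs["IRD"] = DistributionSpec(
            "triangular", {"lo": lo, "mode": (lo + hi) / 2.0, "hi": hi}
        )
    inputs["EF"] = DistributionSpec("uniform", {"lo": 30.0, "hi": 180.0})
    inputs["BW"] = DistributionSpec(
        "normal_truncated", {"mean": 60.0, "sd": 10.0}, bounds=(40.0, 100.0)
    )
    return MCConfig(
        inputs=inputs,
        n_iter=n_iter,
        seed=seed,
        exposure=exposure or default_exposure(),
        toxicity=toxicity or default_toxicity(),
    )
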