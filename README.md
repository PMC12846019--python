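# pte-risk

Contamination screening and dietary health-risk assessment for potentially
toxic elements (PTEs: As, Hg, Pb, Cd, Cu) in medicinal decoction materials.
The package is aimed at food/drug-safety analysts who have batch-level
element concentrations (mg/kg dry weight, with non-detects) for materials in
three classes — roots and rhizomes, aboveground plant parts, and
animal-derived pieces — and want regulatory pollution indices, USEPA-style
chronic risk estimates, and a probabilistic (Monte-Carlo) assessment with
sensitivity analysis.

## Model

Non-detects (below the analytical LOD) are imputed as LOD/2. Per element,
the single-factor pollution index compares the concentration C to its
pharmacopoeia limit S (with species-specific overrides for *Sepiae
Endoconcha* and *Hirudo*):

    P_i = C / S          (<=1 non | <=2 slight | <=3 moderate | >3 heavy)

and the Nemerow composite index combines the mean and maximum over the five
elements:

    P_N = sqrt((P_mean^2 + P_max^2) / 2)
    (<=0.7 safe | <=1 alert | <=2 slight | <=3 moderate | >3 heavy)

Health risk uses the chronic-intake model with element-specific decoction
transfer rates t (the fraction extracted into the drunk decoction):

    THQ = EF * ED * IRD * C * t * 1e-3 / (RfD * BW * AT)
    HI  = sum of the five THQs
    CR  = EF * ED * IRD * C * t * CSF * 1e-3 / (BW * AT)   (As, Pb, Cd)

with EF = 90 d/y, ED = 20 y, BW = 60 kg, AT = 25550 d, IRD the material's
daily dose in g/day. HI < 1 means no expected non-carcinogenic effect; CR in
1e-6..1e-4 is conventionally acceptable. The Monte-Carlo module samples
concentrations, IRD, EF and BW from configurable distributions, propagates
them through the same equations, and ranks uncertainty drivers by
contribution to variance (normalized squared Spearman rank correlation).

A calibrated synthetic-survey generator (lognormal cells with Bernoulli
censoring, truncation at observed maxima, and rare extreme "hotspot"
batches) makes the whole pipeline testable without access to raw survey
data.

## Worked example

```
python analysis/01_simulate.py        # 422 batches, 59 materials
python analysis/03_pollution_indices.py
python analysis/05_monte_carlo.py
```

prints (seed 20250):

```
batches with any P_i > 1: 95 of 422
  heavy (P_i > 3): 12
  moderate (2 < P_i <= 3): 19
  slight (1 < P_i <= 2): 64
materials above alert level (P_N > 0.7): 6
  Aspongopus                               P_N=1.48 (slight)
  ...
roots_rhizomes   P(HI>1)=0.00%  P(CR>1e-6)=74.07%  P(CR>1e-4)=0.00%  CR p95=9.32e-06
aboveground      P(HI>1)=0.00%  P(CR>1e-6)=64.14%  P(CR>1e-4)=0.00%  CR p95=6.81e-06
animal           P(HI>1)=0.00%  P(CR>1e-6)=99.48%  P(CR>1e-4)=0.77%  CR p95=5.35e-05
```

Read: with the synthetic survey, 95 of 422 batches exceed at least one limit
(animal-derived materials dominate); no material reaches HI = 1, so chronic
non-cancer risk is acceptable, while the lifetime cancer-risk distribution
sits almost entirely inside the 1e-6..1e-4 "acceptable" band, crossing 1e-6
with high probability for animal-derived pieces. The sensitivity table shows
As concentration and daily intake as the dominant uncertainty drivers.

The same pipeline runs on real data via the CLI:

```
pte-risk simulate --seed 0 --out batches.csv
pte-risk analyze --batches batches.csv --doses batches.doses.yaml --out-dir bundle/
pte-risk report --bundle bundle/
```

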