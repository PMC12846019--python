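# Methods

## Censored concentrations

Batch tables carry an explicit non-detect marker per cell. Internally every
record keeps a boolean detection flag alongside the concentration, so
summaries can be computed on raw or imputed data. Imputation follows the
simple-substitution convention for left-censored environmental data:
`C = LOD/2`. Default LODs (mg/kg): As 1.0e-4, Hg 3.0e-6, Pb 1.2e-4,
Cd 3.0e-6, Cu 0.02. The Hg and Cd values are unusually low for spectrometric
methods; they are stored as configured defaults and can be overridden in the
registry file if they turn out to be transcription artifacts of the source
method sheet. Reported ranges use raw data with non-detects shown as 0
(matching how censored surveys print zero minima); means, indices and risk
always use the substituted values. A `mean_nd="zero"` flag computes means
with zeros instead, since survey reports rarely state which convention they
used.

## Pollution indices

`P_i = C/S` with the material-resolved limit set; default limits (mg/kg)
As 2, Hg 0.2, Pb 5, Cd 1, Cu 20, with species overrides for *Sepiae
Endoconcha* (As 10, Cd 5) and *Hirudo* (As 5, Hg 1, Pb 10). Material lookup
is exact after whitespace normalization and case folding — no fuzzy
matching, because a silently mismatched species limit is worse than a
default. `P_N = sqrt((mean^2 + max^2)/2)` over the five `P_i`. Class-band
boundaries belong to the lower class (P_i = 1 is "non-pollution"), and
exceedance counting is strict (`C > S`), consistent with `P_i > 1` being the
pollution condition. Batch-level `P_i` drives contamination counts;
material-level `P_N` defaults to the mean-concentration profile (one index
per material), with an element-wise-max mode for conservative screening —
published material indices rarely state which aggregation they used, so both
are provided and neither is asserted as canonical.

## Health risk

THQ/HI/CR as in the README. Numerical notes:

- IRD is g/day and concentrations mg/kg, so the 1e-3 factor is exactly the
  g-to-kg conversion and THQ is dimensionless.
- The same 70-year averaging time (AT = 25550 d) is used for the
  non-carcinogenic and carcinogenic quotients. Conventional USEPA practice
  uses ED*365 for non-cancer AT; here the intermittent-intake calibration
  keeps one AT for both, and the conventional variant is available by
  passing a different `ExposureParams`.
- Elements without a slope factor (Hg, Cu) raise on `cancer_risk` rather
  than returning 0, and are excluded from `CR_total`, to prevent silent
  misuse.
- `CR = THQ * RfD * CSF` holds identically and is exploited as a test
  oracle.
- Band labels: HI < 1 "acceptable"; CR <= 1e-6 "negligible", <= 1e-4
  "acceptable", above "significant".

## Synthetic survey generator

Each (category, element) cell is a mixture: with probability `1 - detect_p`
the batch is non-detected (independent Bernoulli mask rather than
thresholding at LOD, so detection rates can be matched exactly even when the
concentration mass sits far above the LOD); detected values are lognormal,
truncated at the cell's observed maximum by inverse-CDF transform; rare
"hotspot" components inject extreme batches (animal As up to 27.18 mg/kg,
animal Pb up to 55 mg/kg, probability 0.004 each) because a single lognormal
cannot produce both the observed cell means and maxima an order of magnitude
above them.

Calibration is deterministic: from a target (mean, SD, detection rate) the
detected-part moments follow from the Bernoulli mixture, the lognormal shape
from moment matching, and the log-location is then solved (Brent's method on
the closed-form truncated-lognormal mean) so that truncation and hotspots
leave the expected cell mean exactly on target. At n = 10,000 per cell the
generated detection rates land within ~1% and means within ~2% of target;
SDs come out 10-25% low because truncation narrows the tail, which is
accepted — the acceptance checks pin detection rates and means.

Default survey size: 177 roots/rhizomes + 170 aboveground + 75 animal
batches over 24 + 28 + 7 = 59 materials, assigned cyclically. Per-material
daily doses are deterministic placeholders in 3-15 g/day (real doses come
from an external pharmacopoeia and must be supplied for any comparison to
real risk figures). The generator does **not** model inter-element
correlation, spatial/source structure, or material-specific concentration
differences within a category — passing tests therefore demonstrate correct
propagation of censored, right-skewed, truncated concentration data, not
fidelity to any particular real survey.

## Monte-Carlo assessment

Per category, iteration i draws the five concentrations, IRD, EF and BW
independently and evaluates HI and total CR with ED, AT, t, RfD, CSF fixed.
Defaults (assumptions, all overridable per input):

- `C_e`: lognormal moment-matched to the arithmetic mean/SD of the
  category's substituted concentrations, truncated at 1.5x the observed
  maximum. Matching on log-moments was rejected: the LOD/2 pseudo-values
  (down to 1.5e-6 mg/kg) dominate the log scale and blow up sigma_log until
  the implied right tail exceeds 1e4 mg/kg.
- `IRD`: triangular over the category's material dose range, mode at the
  midpoint.
- `EF`: uniform on 30-180 days/year.
- `BW`: normal(60, 10) truncated to 40-100 kg.

Exceedance probabilities are strict empirical fractions; sensitivity is
contribution to variance, `100 * rho_j^2 / sum_k rho_k^2` with Spearman
rank correlations against the output (the convention of spreadsheet risk
add-ins); point-mass inputs contribute 0 by definition, and a constant
output is an error rather than a row of zeros. Degenerate (all-point)
configurations reproduce the deterministic model to machine precision,
which the tests use as an oracle. 10,000 iterations give a binomial
standard error of ~0.5% on probabilities near 50%.

## Determinism

Every stochastic component takes one integer seed (generator spec, MC
config, CLI flags); sampling order is fixed (categories, then elements, then
the canonical input order), so equal seeds give byte-identical CSV/JSON
outputs. The CLI writes a manifest per run recording parameters, seeds,
package version and output files.

## Known limitations

- Placeholder doses mean deterministic HI/CR values are illustrative until
  real per-material IRDs are supplied.
- Total concentrations only; no speciation adjustment (risk assumes the
  most toxic species), no bioaccessibility correction beyond the decoction
  transfer rates.
- Independence of MC inputs; no stated correlation structure is modelled.
- The synthetic spec is one of many consistent with cell-level summary
  statistics; it is an emulation, not a reconstruction.
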