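# Methods

## The dilution model

A single oral dose of D3-creatine (default 0.03 g) is assumed fully
absorbed, with the retained fraction incorporated into the whole-body
creatine pool and converted — like endogenous creatine — to creatinine at a
constant fractional rate. At isotopic steady state (sampling ~96 h after
dosing) the urinary enrichment ratio `er = D3Crn/(D3Crn + Crn)` equals the
tracer fraction of the pool, so

```
pool [g] = (dose_g − spill_mg/1000 · 131.1/134.1) / er
```

where the molecular-weight ratio converts the spilled deuterated mass to
unlabelled-creatine equivalents, and `spill_mg` is the part of the dose
excreted directly in urine. Two empirical spillage parameterisations are
implemented, both log-linear in the urinary creatine/creatinine ratio
r = Cr/Crn:

* single-curve: `spill = exp(1.2913·ln r + 0.7783)·30` mg. This crosses
  the full dose at r = exp((ln(134.1/131.1) − 0.7783)/1.2913) ≈ 0.5570, so
  higher ratios yield negative pools; estimates carry `NEGATIVE_MASS` /
  `SPILLAGE_EXCEEDS_DOSE` flags and are never clipped or imputed, because
  the sign is diagnostic of the spillage model failing, not of the data.
* three-tier: zero below r = 0.015, `exp(0.9424·ln r − 0.1314)·30` on
  [0.015, 0.15], `exp(1.6246·ln r − 1.895)·30` above. The boundary 0.15 is
  assigned to the middle tier, matching the printed inequality directions
  and keeping the map total (r = 0 falls in the zero tier, avoiding ln 0).
  Two honest quirks are preserved rather than smoothed: the map jumps
  *downward* just above r = 0.15, and the top tier crosses the full dose at
  r ≈ 3.256 (far outside the physiological range), so "the modified
  correction never yields negative mass" holds only for r below that
  crossover. Tests assert positivity over r ∈ (0, 2] and the analytic
  crossover location.

Mass estimators divide the pool by an assumed muscle creatine concentration
of 4.3 g/kg. The single-curve spillage formula is undefined at r = 0; below
a configurable floor (default 1e-6) it returns 0 mg with a warning, the
formula's r→0 limit.

## Volume estimators

The spillage-free estimators are linear models calibrated against MRI
fat-free thigh + erector-spinae volume (voxels with < 50% fat):

```
d3cr_ht_wt [L] = 0.032·pool_g + 0.030·weight_kg + 4.336·height_m − 4.134
mv_ht_wt  [L] = 0.045·weight_kg + 6.266·height_m − 5.438
```

with `pool_g = dose/er` (uncorrected — the point of the design is to avoid
the spillage model entirely). Whole-body muscle volume, when wanted, is the
compartment volume divided by 0.45, the roughly constant fraction of
whole-body muscle in thigh + erector spinae of healthy adults.

All constants live in a frozen, YAML-serialisable `ConfigProfile`
(`iwhp2025` is the shipped default carrying the published calibration);
units are fixed at g (pool), mg (spillage), kg (mass, weight), m (height),
L (volume), with the mg/g conversion in exactly one place.

## Calibration pipeline

Cohorts are split into training and validation sets. Two split methods are
provided: `exact` (a random partition with round(n·f) training records,
default f = 0.8) and `bernoulli` (per-case assignment with probability f,
the behaviour of menu-driven packages' "approximately 80% of cases" random
selection, under which realised sizes such as 367/84 from n = 451 arise
naturally even though round(451·0.8) = 361). Simple random splitting, not
stratified — a deliberate default given no evidence the original split was
stratified.

Model fitting is OLS (statsmodels), with ethnicity expanded to indicators
against a Chinese reference, two-sided p-values throughout, and variance
inflation factors computed by auxiliary regressions (VIF_j = 1/(1 − R²_j);
screening threshold 3). Stepwise selection is bidirectional by p-value:
enter the best candidate below p = 0.05, drop any included term at or above
p = 0.10, iterate to stability with an audit log; ethnicity enters and
leaves as a block (its best indicator p decides). Selection is by these
p-value rules alone — the adjusted R² of a larger rejected model may
slightly exceed the selected one's, and no reconciliation is attempted. BMI
is accepted as a column but excluded from the default candidate set (height
and weight separately are more informative); it can be force-included.
Records missing the MRI response are dropped complete-case with a logged
count.

## Agreement analysis

Differences are oriented estimate − reference, so positive bias means
overestimation. Limits of agreement use the conventional 1.96·SD multiplier
(not a t quantile; configurable). The bias CI uses the t distribution with
SE = SD/√n; each limit's CI uses the large-sample SE = SD·√(3/n) with a t
(default) or z multiplier, the variant recorded in the result. Bland–Altman
is refused across units (a kg mass estimate against an L reference);
unit-mismatched methods are compared by correlation only. Correlation
comparison across methods is descriptive (no Steiger/Fisher test), and
group comparisons use pooled-variance t tests (Welch by option) and
Pearson chi-square without continuity correction.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with defaults
fixed once:

| quantity | default | basis |
|---|---|---|
| height | N(1.56, 0.06) m | observed marginal |
| weight | N(59.5, 10.8) kg, corr 0.4 with height | marginal; correlation assumed |
| age | N(62.6, 5.9) y | observed marginal |
| ethnicity | Chinese .816 / Indian .082 / Malay .060 / Other .042 | observed proportions |
| pool | N(75, 12) g, truncated > 20 g | back-derived from mean mass 16.2 kg × 4.3 ≈ 70 g; an assumption |
| MRI volume | linear model + N(0, σ) | σ solved so population R² = 0.576 |
| Cr/Crn ratio | lognormal(ln 0.05, 1.0) with 1% heavy component lognormal(ln 0.8, 0.5) | assumed; heavy tail makes ~1–2% of ratios exceed the 0.557 negative-mass threshold |
| creatinine | lognormal(ln 1e6, 0.6) ng/mL | typical urinary range |
| handgrip | 22 ± 5 kg, corr 0.5 with MRI volume | assumed |

σ is solved from `Var(signal)/(Var(signal)+σ²) = R²_target` with the signal
variance computed analytically from the coefficients and the
anthropometric covariance (population R²; at n = 367 the adjusted/plain
distinction is ≪ the Monte-Carlo noise). Urinary chemistry is
self-consistent by construction: `d3crn = crn·er/(1−er)` with
`er = dose/pool`, so the enrichment→pool round trip is exact and only the
Cr/Crn ratio injects spillage noise. The MRI volume's resulting marginal SD
(~0.80 L) is smaller than a real cohort's (~1.0 L) because the generator is
anchored to the regression structure, not to the volume marginal; likewise
the generated mean volume (≈6.82 L) sits slightly below the anthropometric
estimator's value at the generating means (7.01 L). Out-of-range draws
(height ≤ 1.2 m, weight ≤ 30 kg, pool ≤ 20 g) are redrawn, not clipped.

What passing tests on these cohorts show: the pipeline's algebra,
selection behaviour and unbiased coefficient recovery under the assumed
noise structure. What they do not show: performance under real urinary
chemistry (diet- and renal-function-driven), MRI segmentation error
structure, stratified sampling, or any population other than the one whose
marginals are emulated.

For the stepwise fixture, a borderline age effect is *constructed*, not
drawn: OLS linearity means adding `X·δ` to the response shifts each
coefficient estimate by exactly δ with residuals and SEs unchanged, so δ is
solved to place the realised full-model p-values of age and the ethnicity
contrasts at 0.076, 0.317 and 0.942. A merely simulated p ≈ 0.08 effect
would fall below 0.05 in roughly four of ten replicates, making selection
tests a coin flip; the constructed fixture keeps them deterministic.

## Problem sizes and numerical choices

Coefficient-recovery checks average 100 independently seeded training
cohorts of n = 367; at the solved noise level the seed-averaged height
coefficient has Monte-Carlo SE ≈ 0.05 L/m, so the 2% acceptance band is
tight but attainable. Coverage checks use 1000 replicates of n = 84.
Brute-force scans of the negative-mass sign use step 1e-4 over r ∈ (0, 2].
CSV round trips are bit-exact (full-precision serialisation,
`float_precision="round_trip"` parsing). Splits, cohorts and all stochastic
tests are seeded; hypothesis property tests run derandomised.

## Known limitations

No tracer kinetics over time (steady state is assumed), no renal-function
adjustment, no repeated-measures or proportional-bias Bland–Altman
variants, no regularised regression or cross-validation beyond the single
train/validation split, and no simulation of MRI acquisition error beyond
additive Gaussian noise. The published validation-cohort statistics
(r ≈ 0.81 against MRI, bias ≈ 0.11 L) depend on the original study data;
on synthetic cohorts the package reproduces the *qualitative* structure —
the pool-augmented estimator out-correlates the anthropometric-only and
spillage-corrected alternatives, and becomes exact as reference noise
vanishes — with quantitatively similar values at the default settings.
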