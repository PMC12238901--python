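# d3cr — urinary deuterated-creatine dilution estimation of muscle mass

Skeletal muscle mass is hard to measure in the community: MRI is accurate
but expensive, while DXA and bioimpedance mix muscle with skin, connective
tissue and water status. The deuterated-creatine (D3Cr) dilution method
needs only a 30 mg oral tracer dose and a few drops of fasted urine a few
days later. Because essentially all creatine resides in skeletal muscle and
is converted to creatinine at a constant fractional rate, the urinary
enrichment ratio

```
er = D3Crn / (D3Crn + Crn)
```

measures how far the tracer was diluted, giving the whole-body creatine
pool, `pool [g] = dose [g] / er`, and from it muscle mass.

This package implements the full computational pipeline around that idea,
aimed at analysts running D3Cr substudies (particularly in midlife women,
where tracer "spillage" — dose excreted without entering muscle — is larger
and more variable than in men):

* **Quantitation** — raw LC-MRM peak areas to concentrations, including the
  M+2 isotopologue response-ratio correction for creatinine (default factor
  0.002469) and internal-standard normalisation, plus assay QC (RSD
  precision, percent bias).
* **Estimators** — four muscle estimates per participant:
  - `d3cr_original` (kg): `pool = (0.030 − spill·131.1/134.1/1000)/er`,
    `spill = exp(1.2913·ln(Cr/Crn) + 0.7783)·30` mg, mass = pool/4.3;
    negative masses at high urinary creatine are flagged, never clipped;
  - `d3cr_modified` (kg): the three-tier spillage variant (no correction
    below Cr/Crn = 0.015; two log-linear tiers above);
  - `d3cr_ht_wt` (L): the spillage-free fat-free thigh + erector-spinae
    volume estimator
    `0.032·pool + 0.030·weight[kg] + 4.336·height[m] − 4.134`;
  - `mv_ht_wt` (L): anthropometric-only,
    `0.045·weight + 6.266·height − 5.438`.
  Whole-body muscle volume is obtained as compartment volume / 0.45.
* **Calibration** — train/validation splitting, stepwise OLS with VIF
  screening (statsmodels underneath), emitting coefficient sets compatible
  with the estimators.
* **Agreement** — Pearson correlations against an MRI reference and
  handgrip strength, Bland–Altman bias and limits of agreement with
  confidence intervals, train-vs-validation group tests.
* **Synthetic cohorts** — a seeded generator reproducing the cohort
  structure the method assumes (correlated anthropometrics, pool-driven MRI
  volumes at a chosen R², self-consistent urinary chemistry with a
  heavy-tailed Cr/Crn mixture), so the entire pipeline can be exercised and
  tested without access to any study data.

## Worked example

```python
from d3cr import UrineMeasurement, estimate_all

u = UrineMeasurement(crn=1.2e6, d3crn=480.0, cr=6.0e4)  # ng/mL
for e in estimate_all(u, weight_kg=59.5, height_m=1.56):
    print(e.method, round(e.value, 3), e.unit)
```

prints

```
d3cr_original 16.673 kg
d3cr_modified 16.56 kg
d3cr_ht_wt 6.816 L
mv_ht_wt 7.014 L
```

The enrichment ratio here is 480/(1.2e6 + 480) ≈ 4.0e-4, so the uncorrected
pool is 0.03/4.0e-4 ≈ 75 g. The Cr/Crn ratio of 0.05 implies 1.36 mg
(original) or 1.56 mg (modified) of spilled dose, giving the slightly
smaller corrected pools behind the two mass estimates (≈16.6 kg of total
muscle). The two volume estimates (≈6.8–7.0 L) are fat-free thigh +
erector-spinae volumes; divide by 0.45 for a whole-body figure.

The same pipeline runs from the shell:

```sh
d3cr --seed 7 simulate --n 451 --out cohort.csv --truth truth.csv
d3cr estimate --in cohort.csv --out estimates.csv
d3cr --seed 7 calibrate --in cohort.csv --mode d3cr_ht_wt --out coef.yaml
d3cr evaluate --in estimates.csv --cohort cohort.csv --out report.csv --plots figs/
```

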