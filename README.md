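# ccmquant

Absolute quantification of the central carbon metabolome from targeted
tandem-MS peak areas.

Targeted LC-MS/MS and ion-chromatography MS/MS experiments report integrated
peak areas, not concentrations. Turning those areas into absolute
intracellular metabolite concentrations requires a chain of corrections that
is easy to get subtly wrong: isotope-dilution correction against a labeled
internal standard, weighted calibration curves with a defensible
quantification range, correction for dilution/concentration steps during
sample preparation, and normalization to the amount and volume of sampled
biomass. `ccmquant` implements that chain as a tested, scriptable pipeline
for a 68-metabolite panel of central carbon metabolism (glycolysis, pentose
phosphate pathway, TCA cycle, the 20 proteinogenic amino acids, and the
(deoxy)nucleoside mono-/di-/triphosphate pools), together with the
quality-control metrics and downstream statistics such studies report.

It is aimed at analytical/quantitative metabolomics groups who want a
transparent, open re-implementation of this workflow — and a synthetic study
generator with known ground truth to validate it end to end.

## The model

For analyte *m* in sample *s*, the measured response ratio is

    y(s,m) = A_analyte(s,m) / A_IS(s,m)

where both areas share the same multiplicative matrix/ionization factor, so
the ratio cancels it (the isotope-dilution premise). Calibration standards
at concentrations x₁…x_k are fit by weighted least squares,

    min Σᵢ wᵢ (yᵢ − a − b·xᵢ)²,   wᵢ = 1/xᵢ,

and the quantification range [LLOQ, ULOQ] is the span of calibrants whose
back-calculated concentration is within ±20% of nominal (±25% at the lowest
level). Sample ratios are interpolated, corrected for preparation factors
(IS spike dilution 1/(1−f), lyophilization/reconstitution), and normalized:

    microorganisms:  c_int = c_extract · V_extract / (DW · v_spec)      [v_spec in L/g]
    cell lines:      c_int = c_extract · V_extract / (N_cells · V_cell) [V_cell measured, pL]

QC: the adenylate energy charge EC = ([ATP] + ½[ADP]) / ([ATP]+[ADP]+[AMP])
must fall in the physiological band 0.7–0.95, and single-replicate outliers
are rejected by Dixon's Q (two-tailed r₁₀, n ≤ 10). Statistics: >50%
prevalence filter, minimum-value imputation, auto-scaling, PCA with 95%
confidence ellipses, pooled-variance t-tests with Benjamini–Hochberg FDR,
log₂ fold changes, class-composition and order-of-magnitude summaries.

## Worked example

Run the full pipeline on the default synthetic study (8 biological groups —
4 microorganisms including 2 proline-rich microalgae, 4 human cell lines —
× 5 replicates × 68 metabolites, 10% detector CV, 30% matrix-effect SD, 4%
missingness):

```python
from ccmquant.pipeline import PipelineConfig, run_pipeline

bundle = run_pipeline(PipelineConfig.default(seed=74))
print(bundle["qc"].ec_table.round(3))
```

```
              ec_mean  ec_sd  n_replicates  ec_in_range
group_id
bsubtilis       0.841  0.014             3         True
hek293          0.862  0.013             5         True
helas3          0.867  0.025             4         True
mccar           0.778  0.010             2         True
nb4             0.786  0.015             5         True
noceanica       0.784  0.027             5         True
ptricornutum    0.855  0.036             4         True
scerevisiae     0.744  0.031             4         True
```

Every group's pipeline-recovered energy charge sits inside the 0.7–0.95
physiological band (`n_replicates` counts replicates with all three
adenylates quantified after outlier rejection and missingness). The recovery
against the generator's ground truth:

```python
print(bundle["manifest"]["median_abs_relative_recovery_error"])  # 0.053
```

i.e. the median recovered intracellular concentration is within ~5% of
truth under realistic noise. A calibration model and a class-composition
slice, from the same run:

```
AMP calibration: slope=7.11e+03  r2=0.9936  LLOQ=3.45e-09 M  ULOQ=1.15e-04 M

 group_id                 met_class  percent
noceanica                amino_acid     88.5
noceanica      nucleoside_phosphate      4.7
noceanica        organic_acid_other      4.9
...
```

The amino-acid dominance of the proline-rich alga group is the generator's
built-in biology showing through the full quantification chain.

The same pipeline is available from the shell:

```
ccmquant run --seed 74 --outdir out/          # all tables + run_manifest.json
ccmquant simulate --seed 74 --outdir sim/     # raw peaks, biomass, ground truth
ccmquant run --seed 74 --no-isotope-correction --outdir out_ablation/
```

The ablation flag quantifies on raw analyte areas instead of IS-corrected
ratios; on the same seed the recovery error roughly doubles, which is the
quantitative argument for isotope dilution.

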