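# Methods

## Scope and data flow

`ccmquant` starts at integrated peak areas (long-format tables of analyte
and internal-standard channels per sample and metabolite) and ends at
intracellular molar concentrations with QC and statistics. Peak integration,
chromatography and vendor raw files are out of scope. The stages are:

1. **Isotope-dilution correction** (`quantify.corrected_response`): each
   analyte area is divided by its internal-standard (IS) area. The model
   assumption is that matrix/ionization effects act multiplicatively and
   identically on both channels of a given (sample, metabolite), so the
   ratio cancels them. The IS is a matched U¹³C/¹⁵N isotopologue for
   phosphorylated metabolites and TCA intermediates (capillary IC method), a
   U¹³C-labeled whole-cell extract for organic acids, and a labeled
   amino-acid mixture for the 20 proteinogenic amino acids.
2. **Weighted calibration** (`quantify.fit_calibration`): corrected
   responses of a serial-dilution standard series are fit by least squares
   with 1/x weights (x = nominal calibrant concentration). The blank is
   excluded from the fit (1/x is undefined at 0). The quantification range
   is bounded by back-calculation accuracy: LLOQ is the lowest calibrant
   whose back-calculated concentration is within ±20% of nominal (±25%
   allowed at the lowest level), ULOQ the highest within ±20%. This is the
   conventional bioanalytical acceptance rule, adopted here as an explicit
   package convention. Values outside the range are reported but flagged,
   and the statistics layer treats them as missing.
3. **Preparation factors** (`quantify.PrepFactors`): spiking f (v/v) of IS
   dilutes the analyte by (1−f) — 20% for the labeled-extract methods, 5%
   for the amino-acid mix — and lyophilization/reconstitution contribute a
   net concentration factor. Defaults encode a 10× lyophilization
   concentration; these are config inputs, not derived quantities.
4. **Biomass normalization** (`biomass`): microorganism samples are
   normalized to sampled dry weight and converted to molarity with a
   literature specific cell volume (L/g); cell-line samples are normalized
   to counted cells and converted with the replicate's measured cell volume
   (pL, Coulter-type counter). The packaged `cell_models.csv` keeps the
   printed literature values verbatim; the S. cerevisiae specific volume is
   printed with a third-digit rounding discrepancy relative to exact
   division, so its consistency test uses a 0.5% tolerance. The fusiform
   diatom's volume uses the half-parallelepiped model length·width·height/2.
   The conversion assumes all extracted metabolite originates from the cell
   interior and distributes over total cell volume (no compartments, no
   extraction-efficiency correction).

## Quality control

* **Energy charge** EC = ([ATP]+½[ADP])/([ATP]+[ADP]+[AMP]) (Atkinson's
  index; the formula is hard-coded). Per-replicate EC is computed from that
  replicate's quantified adenylates and averaged per group (mean ± SD,
  matching how such studies report it). The physiological band 0.7–0.95 is
  checked with inclusive endpoints — the conservative reading of a printed
  range.
* **Dixon's Q**: the classic r₁₀ statistic, suspect = the end with the
  larger gap/range ratio, compared against two-tailed critical values
  (Rorabacher 1991 tabulation, shipped as a versioned CSV, α ∈
  {0.10, 0.05, 0.01}). At most one rejection per replicate vector, no
  iteration; a zero range yields no test. Rejection operates per
  (group, metabolite) on final intracellular values, before any averaging,
  and rejected values are treated as missing downstream. Empirical type-I
  rate at α = 0.05 on clean normal replicates (n = 5) is ≈ 0.047.

## Statistics

Prevalence filter: a metabolite is kept when quantified in strictly more
than 50% of the biological *groups* (a group counts as covered when ≥ 1
replicate is quantified); a config switch allows per-sample counting.
Imputation: per-metabolite minimum measured value. Auto-scaling: column
mean 0, SD 1 (ddof = 1). PCA (scikit-learn, full SVD) is run on the
filtered→imputed→auto-scaled matrix, in that order; the sign convention
fixes the largest-magnitude loading of each component positive. Per-group
95% confidence ellipses are covariance ellipses scaled by the χ²(2 df)
0.95 quantile; a Hotelling-T² small-sample scaling is available via
`ellipse_method="hotelling"`. Group comparisons use pooled-variance
two-tailed t-tests with Benjamini–Hochberg step-up q-values (`fdr_bh`),
significant at q ≤ 0.05; effect sizes are log₂ fold changes of group means
(undefined for non-positive means, reported absent). Pathway rendering is
replaced by an exported table (metabolite, pathway position, log₂FC,
significance) consumable by any network renderer. Order-of-magnitude
summaries use floor(log₁₀): a decade boundary (1e-3 M) belongs to its own
decade (−3).

## The synthetic study generator

The generator (`synthetic`) emulates the *structure* of a multi-organism
quantitative study so every downstream stage is testable against known
ground truth. Defaults (all overridable in `StudyConfig`):

| parameter | default | meaning |
|---|---|---|
| groups | 8 (4 microorganisms, 2 adherent + 2 suspension cell lines) | biological systems |
| n_replicates | 5 | biological replicates per group |
| noise_cv | 0.10 | lognormal detector noise CV, per channel |
| matrix_effect_sd | 0.30 | lognormal matrix factor SD, shared between channels |
| missing_rate | 0.04 | fraction of (sample, metabolite) cells dropped |
| outlier_rate | 0.02 | per (group, metabolite) chance of one ×3–10 replicate spike |
| biomass_cv | 0.05 | replicate jitter on DW / cell density / cell volume |
| calibration_levels | 1e-3 … 100 (11 levels, relative) | serial dilution of a balanced standard |
| calibration_replicates | 3 | injections per level |
| ec_range | (0.75, 0.93) | ground-truth EC band per group |

Ground truth is drawn log-uniformly per metabolite class with
class-specific locations (deoxynucleoside phosphates lowest, ~10⁻⁸–10⁻⁶·⁵ M;
amino acids highest, shifted up in the eukaryote-like cell-line groups);
proline in the two alga-like groups is drawn at 10⁻¹·³–10⁻¹ M, reproducing
the osmolyte-dominated pool of marine microalgae. This yields ≥ 3 decades of
span within every group and ≈ 7 decades across the panel. Adenylates are
drawn jointly (total pool, target EC, ADP fraction), so the group EC is in
band by construction. The replicate-level biomass CV (5%) is a free
parameter of this artifact; published studies rarely report it.

Peak areas follow `analyte = k_m · c · IS0_m · M · ε`, `IS = IS0_m · M · ε′`
with the matrix factor M shared between channels — this makes the benefit
of isotope dilution measurable: quantifying on raw analyte areas instead of
ratios roughly doubles the median recovery error on the same seed.
Calibration series use the same response model with M = 1, a blank, and IS
spiked as in samples.

Two generator choices deserve explanation:

* **Calibration scale.** A single absolute molar dilution series cannot
  span a panel whose extract concentrations cover ~7 orders of magnitude;
  real laboratories balance their standard mixtures per metabolite. The
  config therefore stores *relative* levels applied to a per-metabolite
  scale (geometric-mean true extract concentration), spanning 10⁻³–10² of
  that scale.
* **Replicate injections.** With a single injection per level, the
  1/x-weighted slope of a series with geometric level spacing is governed
  almost entirely by the top one or two points (the weighted normal
  equations reduce toward slope ≈ Σy/Σx), so a 14% ratio CV propagates into
  per-metabolite slope biases of up to ~17% — not how calibration is run in
  practice. Standards are therefore injected in triplicate by default.

What passing tests on synthetic data do **not** show: the generator has no
chromatographic drift, no carry-over, no saturation/nonlinearity at high
concentration, no correlated batch effects, no extraction-efficiency
losses, and its missingness is completely at random rather than
intensity-dependent. Results on real data depend on exactly those effects;
the synthetic study validates the arithmetic and statistical chain, not the
wet-lab workflow.

## Numerical choices

* The calibration design matrix is rescaled by the top level before the
  WLS solve (statsmodels) and the slope unscaled afterwards; raw molar x
  values (~10⁻¹¹) make the whitened design ill-conditioned enough to break
  the noiseless round-trip contract (max relative error < 10⁻⁹; achieved
  ~10⁻¹⁵).
* Interpolated negative concentrations clamp to 0 and flag `below_lloq`.
* Significant-figure rounding for tabulated comparisons rounds the shortest
  decimal representation half-to-even (1.225e-13 → 1.22e-13), matching how
  printed tables are rounded.
* Zero-variance columns abort auto-scaling with the column named; a fully
  missing column aborts imputation (unreachable after prevalence
  filtering).
* Problem sizes: the default study (8 × 5 × 68, triplicate 11-level
  calibration) runs the full pipeline in ~1 s; oracle-comparison tests use
  100–1000 random instances and the Dixon type-I simulation 10,000
  replicate vectors.

## Known limitations

* The exact identity of every panel member beyond the documented class
  structure (20 amino acids, 12 + 12 nucleotide species, 24 central-carbon
  intermediates) is a curated choice; metabolites quantifiable by more than
  one method are assigned one primary method to avoid double
  quantification.
* Dixon's Q is limited to 3 ≤ n ≤ 10 replicates; larger designs need a
  different outlier test.
* Whether outlier rejection should operate before or after biomass
  normalization is ambiguous in practice; this package tests on final
  intracellular values.
* No batch/drift correction, no database (YMDB/HMDB) lookups, no
  figure-quality graphics.
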