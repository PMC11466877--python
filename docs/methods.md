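# Methods

This note documents the models implemented in `soyshade`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a user may want to revisit.

## Shade-tolerance evaluation

The evaluation chain (module `evaluation`) runs per year:

1. **STC.** For accession *i*, trait *j*:
   `STC_ij = mean(shade replicates) / mean(CK replicates)`. The coefficient
   is stored as a plain ratio (typical values 0–3), with a percent display
   left to the caller. A CK mean of zero flags the cell *undefined*; a
   missing condition flags it *missing*; neither is ever silently set to 0.
   A shade replicate mean of zero (e.g. no branches formed under shade)
   legitimately gives STC = 0.
2. **Subordinate function value.** Min-max standardization of STC within
   each trait-year across the panel. A constant trait (max = min) carries no
   ranking information and is dropped from that year's evaluation with a
   warning, rather than being pinned to an arbitrary midpoint.
3. **Weights.** The F matrix is column-standardized and its correlation
   matrix eigendecomposed. The contribution rate `p_j` of component *j* is
   its eigenvalue share; weights are `W_j = p_j / Σ(retained p_j)`. By
   default all components are retained, which makes `W_j` the eigenvalue
   fractions. "Contribution rate" is read as PCA variance contribution — the
   standard construction for membership-function comprehensive evaluation in
   crop stress-tolerance work; `weight_mode="equal"` bypasses PCA entirely.
4. **D value.** `D = Σ_j u(X_j) · W_j`, with indicators `X_j` the retained
   principal-component scores by default (`indicator="pc_scores"`); a
   config switch (`indicator="sfv"`) uses the trait SFVs directly with
   equal weights, since the literature is not unanimous on which indicator
   enters `u`. `u` is min-max standardization, so D ∈ [0, 1].
5. **ASFV and grading.** ASFV is the unweighted mean SFV across retained
   traits. Grading into HSS < SS < MST < ST < HST is pluggable because
   "evenly divided into five categories" admits several readings and
   published threshold sets are neither exact quintiles nor equal-width
   bins: `quantile` (default, equal fifths; proportions configurable),
   `equal_width` (range/5), and `mean_sd` (cuts at mean + k·σ·(−1.5, −0.5,
   0.5, 1.5), k = 1). Thresholds are always reported so users can compare
   against any published cut points. Grading uses ASFV (not D), matching how
   tolerance classes are usually reported; both scores are always computed.
   A value exactly on a cut falls in the lower class ("high tolerance is
   *above* the top threshold").
6. **Selection.** HST accessions are reported per year sorted by ASFV, with
   their panel percentage to two decimals; the cross-year report is the
   union of HST sets (an accession selected in both years appears once)
   with per-year and mean ASFV.

Evaluation is per-year throughout, because grade thresholds shift between
years; cross-year aggregation happens only at the selection step.

## Phenotype statistics

* `describe` reports max, min, mean, sample SD (n−1), CV% (100·sd/mean,
  undefined at mean 0), and bias-corrected skewness / excess kurtosis (the
  adjusted Fisher–Pearson estimators used by mainstream spreadsheet and
  statistics packages; `bias_correction=False` gives raw moment ratios).
  Kurtosis needs n ≥ 4, skewness n ≥ 3; both are undefined for constant
  input.
* `anova_gxe` is a two-factor fixed-effects ANOVA with interaction
  (genotype × environment), fitted with statsmodels OLS + `anova_lm`.
  Replicates are the plant-level values within accession × condition ×
  year. The environment factor defaults to year with the data restricted to
  one light regime (`condition="CK"`); it can be switched to the light
  condition itself, because published G/E/G×E tables do not always state
  which environment is meant. Balanced data get the type-I decomposition
  (orthogonal there); unbalanced layouts must opt into type II.
* `heritability` computes broad-sense entry-mean H² from expected mean
  squares: σ²ε = MS_error, σ²GE = (MS_GxE − MS_error)/r, σ²G =
  (MS_G − MS_GxE)/(e·r), negatives truncated at 0, then
  H² = σ²G / (σ²G + σ²GE/e + σ²ε/(e·r)) · 100. This formula is the standard
  for multi-environment trials; it is an interpretation, since tolerance
  studies rarely print their H² formula. Note the estimator's sampling
  spread: with 264 accessions, 2 years and 10 replicates a single-trait Ĥ²
  has a Monte-Carlo SD near 7 points, so recovery checks average across the
  six traits (SD ≈ 3 points).
* `correlate` builds the 12-column (6 traits × 2 years) pairwise-complete
  Pearson matrix with p-values and significance stars at p < 0.05; cells
  with fewer than 3 complete pairs are undefined.

## Mixed-linear-model GWAS

The engine (module `gwas`) is written from first principles rather than
wrapping an existing GWAS package.

* **Kinship.** VanRaden genomic relationship,
  `K = ZZ' / (2 Σ p_k(1−p_k))`, Z the dosage matrix centered at 2p_k.
  Missing dosages are mean-imputed per SNP for K only; monomorphic SNPs are
  excluded.
* **REML.** With `K = UΛU'`, rotating by U' makes the covariance of
  `y = Xβ + u + ε` diagonal in `δ = σ²e/σ²g`, and the REML deviance is a 1-D
  function of δ: a 64-point grid on log δ ∈ [−10, 10] locates the basin and
  bounded Brent refinement polishes it (xatol 1e-8). Estimates at the grid
  bound raise a warning flag. δ is only weakly identified when K ≈ I (then
  V ≈ (σ²g+σ²e)I for any δ); this matters for panels of essentially
  unrelated accessions and is why the "no genetic variance ⇒ large δ̂"
  behavior is only reliable for structured kinship.
* **Scan.** Per SNP, GLS effect and Wald t-test under V = σ²g K + σ²e I.
  Default is P3D: δ from the null model is reused for every SNP and the
  residual scale is re-estimated per SNP from the whitened residual sum of
  squares (t with n − q − 1 df); `p3d=False` refits REML per SNP. The two
  agree within 0.2 −log10(p) units for ≥95% of SNPs in simulation.
  `r2_percent` is the SNP's share of the total sum of squares after
  covariates on the whitened (V^{−1/2}) scale — one of several defensible
  definitions of per-SNP variance explained, chosen for its additivity with
  the test statistic. Missing dosages are mean-imputed; SNPs constant after
  imputation or below the MAF threshold (default 0.05) are skipped with a
  reason.
* **Significance and QC.** The significance rule is a fixed −log10(p) ≥ 5.0
  line (inclusive), as is conventional in this literature, not
  FDR/Bonferroni. λ_GC = median(χ²)/0.4549 is reported as calibration QC;
  a Manhattan-ready table (cumulative bp, −log10(p), alternating chromosome
  color index, threshold attached) supports plotting.
* **Phenotype unit.** GWAS runs on per-accession values: condition means
  (CK, shade) and STCs per year. Plant-level GWAS is out of scope. No
  principal-component covariates are included by default (`--pcs k`
  enables them).

## Post-GWAS

* SNP ids follow `S{chrom}_{pos}`; zero-padded chromosomes are accepted on
  parse but never generated. Pairwise distances are reported in bp and in
  kb rounded half-up — the rounding that matches how locus separations are
  conventionally quoted.
* Candidate genes are genes whose 1-based inclusive [start, end] intersects
  [pos − w, pos + w], inclusive at both boundary coordinates, w = 120 kb by
  default (the panel's LD decay range); results are sorted by distance from
  the SNP, 0 for overlapping genes.
* Allele effects compare the two homozygote classes (heterozygotes excluded
  by default, mirroring two-genotype haplotype comparisons; an option pools
  them into the alt class) with a Welch t-test; stars at 0.05/0.01/0.001.
  The favorable allele is the one with the higher mean STC — configurable
  per trait, since a higher shade/CK ratio of plant height could be argued
  unfavorable, but higher-is-favorable is the convention the bundled marker
  panel uses. Ties break to the alt allele with an explicit flag.
* Favorable-allele counting scores homozygous calls matching the favorable
  set; missing calls are skipped and reported, absent markers are an error.

## KASP assembly

`f1 = FAM_TAIL + core + fam_allele`, `f2 = HEX_TAIL + core + hex_allele`,
core = the 20 bases immediately 5′ of the SNP on the design strand (pass the
reverse-complemented flank for a minus-strand design). FAM/HEX-to-allele
assignment is caller-specified — the bundled published assays map FAM to
different alleles at different markers, so no ref/alt or favorable rule is
invented. Validation checks the tail constants, core identity between
forwards, 3′ allele bases, and a primer-dimer heuristic (no shared 12-mer
between the reverse and either forward); the Wallace-rule Tm (2(A+T) +
4(G+C)) is reported as a metric, never enforced — thermodynamic design of
the common reverse primer is upstream of this package and reverse primers
are accepted as inputs.

## Synthetic panels

The generator (module `simulate`) emulates the field trial the analysis
assumes: 264 accessions, 20 chromosomes with 2,000 unlinked biallelic SNPs
(per-SNP alt frequency uniform on [0.05, 0.5], dosages binomial), six
traits, two years × two light regimes × 10 plants. On the log scale, for
trait *j*:

```
log CK(i,j,y,r)    = log(baseline_j) + g_ij + u_ijy + e
log shade(i,j,y,r) = log CK_mean + log(S_j) + Σ_q d_iq·log(ρ_q) + η_ijy + e
```

with g ~ N(0, σ²G) genotypic, u ~ N(0, 0.12) accession × year, η ~ N(0,
0.12) accession × year shade-response noise, e ~ N(0, 0.20) plant-level
residual. σ²G derives from a target entry-mean heritability (default 0.40,
the range reported for shade-tolerance coefficients in this crop):
σ²G = H²/(1−H²) · (σ²GE/e + σ²ε/(e·r)). Base shade multipliers S_j default
to 1.75 and 1.90 for the two height traits (shade elongates them) and
0.90–0.95 for the four count/weight traits (shade depresses them). QTLs act
multiplicatively on the shade/CK ratio (ρ per alt allele), so they surface
in the STC and not in the control trait; `with_planted_qtl` sizes ρ so a
QTL explains a chosen fraction of the log-STC variance, using the
first-order noise variance σ²η + 2σ²ε/r. An optional zero-inflation knob
zeroes a fraction of shade branch counts to exercise the STC = 0 path.

What the generator does **not** emulate: linkage disequilibrium and
population structure (SNPs are exchangeable; K ≈ I), selection, epistasis,
shared environment between neighboring plots, and measurement error beyond
lognormal replicate noise. Consequently, passing tests demonstrate the
correctness and calibration of the statistical machinery — not that the
pipeline's power or candidate-gene yield transfers to a real resequenced
panel, where LD both helps (tag SNPs) and hurts (inflated locus counts).
Two quantitative side effects of the design are worth knowing: (i) ANOVA on
the raw scale of a multiplicative model shifts a few points of genotypic
variance into interaction/error, so recovered H² sits ~3 points below the
log-scale target; (ii) with K ≈ I the REML δ is weakly identified (the scan
is unaffected — with K ≈ I whitening is a rescaling and the SNP test
reduces to OLS).

## Problem sizes and numerics

Default analysis sizes — 264 accessions, 2,000 SNPs, 6 traits, 2 years —
were chosen to match the trial's dimensions while keeping a full pipeline
run (36 scans) under a minute; all simulations are deterministic given the
config seed, and the pipeline manifest records the seed and per-stage row
counts so a rerun is bit-identical. Kinship is symmetrized and its
eigenvalues floored at 0 before use; p-values are floored at the smallest
positive double before taking −log10; SFV and D computations guard
constant columns (dropped and zeroed respectively). Coordinates are 1-based
inclusive everywhere; any half-open arithmetic is internal.

## Known limitations

* The MLM is single-locus; multi-locus models (FarmCPU/BLINK-style) and
  rare-variant tests are out of scope.
* The evaluation drops constant traits instead of imputing a neutral
  membership value; with many undefined STC cells the PCA weights are
  computed on mean-filled standardized scores.
* `anova_gxe` is fixed-effects only; no random-effects/mixed ANOVA.
* KASP validation is rule-based; no genome-wide specificity search and no
  fluorescence-cluster genotype calling.
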