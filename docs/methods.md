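# Methods

## Model and procedure

`smrkit` implements two-sample summary-data Mendelian randomization for
gene expression. The assumed causal diagram is

    variant z  →  expression x  →  trait y

with the z→x arrow measured in a cis-eQTL study, the z→y arrow in an
independent GWAS, and the x→y arrow (`b_xy`) the estimand. With a
single valid instrument the ratio estimate is exact: if `b_zy = b_xy ·
b_zx`, then `b_xy = b_zy / b_zx`, estimated by `b_SMR = b_GWAS /
b_eQTL` at the top cis-eQTL SNP. The test statistic

    T_SMR = z²_GWAS · z²_eQTL / (z²_GWAS + z²_eQTL) ~ χ²₁ (null: b_xy = 0)

is the standard SMR chi-square; it is bounded by the weaker of the two
squared z-scores, making it conservative relative to a plain Wald test
on the ratio but robust to a weak instrument on either side. Squared
z-scores come from beta/SE when available; otherwise from the two-sided
p-value via the upper-tail normal quantile at p/2 (accurate to
p = 1e-300; censored entries like `<1.00E-300` are clamped to the bound
and flagged). Both inputs carry three significant figures in published
tables, which is why the bundled case-study reproduction is asserted at
5% relative tolerance.

The SMR null hypothesis is "no association"; a rejection does not
distinguish one shared causal variant (pleiotropy) from two linked
variants. HEIDI tests the single-causal-variant null: for each non-top
instrument i, `d_i = b_SMR(i) − b_SMR(top)` should be zero in
expectation. The covariance of the `d` vector follows from the
first-order delta method for ratios with, within each study,
`cov(b_i, b_j) = r_ij · se_i · se_j` (r from reference-panel dosage
correlations, signed) and zero covariance across the two studies
(independent cohorts). `T_HEIDI = Σ (d_i/SE(d_i))²` is referred to
`Σ λ_k χ²₁` with λ the eigenvalues of the correlation matrix of `d`.

## Tail probabilities of quadratic forms

The weighted-chi-square tail is computed by Imhof's exact inversion of
the characteristic function (adaptive quadrature on `[0, ∞)`; the
integrand oscillates indefinitely, so the quadrature's subdivision
limit is raised to 500 and its absolute-error estimate is checked). If
the quadrature fails or reports error above 1e-5, the code falls back
to the Satterthwaite two-moment scaled-chi-square approximation and
logs that it did so. The test suite checks the Imhof path against
100,000-draw Monte Carlo on random eigenvalue sets (3 MC standard
errors) and against closed forms for single and equal weights.

## Thresholds and defaults

| parameter | default | meaning |
|---|---|---|
| `p_eqtl_max` | 5e-8 (inclusive) | top-eQTL eligibility for SMR |
| `maf_min` | 0.01 (strict <) | minimum MAF in all three sources |
| `freq_diff_max` | 0.2 (inclusive) | max pairwise effect-allele-frequency difference, all three source pairs |
| `r2_min`, `r2_max` | 0.05, 0.90 | LD window (vs top SNP, and pairwise) for HEIDI instruments |
| `heidi_instrument_p` | 1.57e-3 | max eQTL p for a HEIDI instrument (≈ \|z\| > 3.16) |
| `min_snps`, `max_snps` | 3, 20 | HEIDI instrument count bounds |
| `alpha`, `heidi_alpha` | 0.05 | Bonferroni numerator; HEIDI retention threshold |
| panel QC | call rate ≥ 0.95, MAF ≥ 0.05, HWE p ≥ 1e-6, individual call rate ≥ 0.95 | applied in that order |

Design choices where the convention was genuinely open:

- **Cis window** is strict: `|snp_pos − probe_pos| < 1 Mb`.
- **Bonferroni denominator** counts probes with a valid SMR p-value;
  probes whose top eQTL misses eligibility consume no budget (this is
  what lets the threshold differ between GWAS datasets analyzed against
  the same eQTL panel).
- **HEIDI gating** is sequential: HEIDI is evaluated only for
  Bonferroni survivors, and survival requires `p_HEIDI ≥ 0.05`
  (rejection = heterogeneity = linkage).
- **HWE criterion** removes variants with departure p < 1e-6; the
  chi-square goodness-of-fit test is used rather than the exact test
  (deterministic, closed-form, adequate at panel scale); monomorphic
  variants return p = 1 by convention.
- **Strand-ambiguous SNPs** (A/T, C/G): orientation is resolved by
  matching the reported frequency against the panel; SNPs with
  min(f, 1−f) > 0.4 in any source are dropped as undecidable. Other
  pairs are aligned by label, with a complement-strand retry.
- **Ties** in top-SNP selection break by larger |z_eQTL| then
  lexicographic snp_id; instrument pruning is greedy in eQTL-strength
  order so the weaker member of an out-of-window pair is dropped.
- **Degenerate inputs**: `b_eQTL = 0` invalidates the instrument
  (error); `b_GWAS = 0` yields `b_SMR = 0` with SE reported absent
  (delta expansion degenerate); a numerically singular d-correlation is
  ridge-regularized (+1e-8 on the diagonal, logged).

## Synthetic data

The generator emulates the three data sources the pipeline consumes —
an expression cohort, an independent trait cohort, and an independent
reference panel — over a single cis locus of 20 SNPs with MAFs evenly
spaced over [0.1, 0.5].

LD uses a Gaussian copula: a latent normal vector with AR(1)
correlation `rho^|i−j|` (default rho = 0.9) is thresholded at the MAF
quantile once per haplotype and two haplotypes are summed. Thresholding
attenuates dosage-level correlation below the latent rho by a factor of
roughly 0.75–0.8 at these MAFs; the attenuation is measured by the
tests rather than assumed. Under the linkage architecture the second
causal variant is placed two SNPs from the first, where the measured
dosage correlation is ≈ 0.6.

Phenotypes are quantitative: expression `x = b_zx·g + N(0,1)` (default
b_zx = 0.3, i.e. a strong brain-eQTL-scale effect giving z ≈ 14 at
n = 5,000) and, under pleiotropy, trait `y = b_xy·(b_zx·g) + N(0,1)`
with default b_xy = 0.3; under linkage `y = b_zy2·g₂ + N(0,1)` with
b_zy2 = 0.15; under null `y` is pure noise. A quantitative (liability-
scale) trait rather than case/control keeps the IV identity exact and
the calibration interpretable; meta-analytic GWAS betas are on mixed
scales anyway. One causal eQTL variant per probe matches the HEIDI
null. Summary statistics are per-SNP simple least squares (t-based
two-sided p, n−2 df).

What the generator does **not** emulate: case/control ascertainment,
population stratification, imputation error, multi-causal expression
architectures, allele-frequency drift between cohorts, and trans-eQTLs.
Passing tests therefore certify the statistics and plumbing under the
stated model, not robustness to those real-data complications.

## Validation experiments and problem sizes

The experiment sizes were chosen to make binomial/Monte-Carlo error
small relative to the bands being checked:

- **2SLS identity**: one cohort (n = 4,000) measured for both x and y;
  summary-level `b_SMR` equals the individual-level two-stage ratio
  to machine precision (they are algebraically identical with one
  instrument).
- **SMR type-I error**: 2,000 null replicates, 5,000 per cohort;
  empirical rejection at 0.05 must fall in [0.035, 0.065]. The
  measured rate sits slightly below 0.05, consistent with the
  statistic's min-bound conservatism at finite eQTL strength.
- **HEIDI size/power**: 2,000 replicates each; size under pleiotropy
  in [0.03, 0.08], power under linkage (r ≈ 0.6, b_zy2 = 0.15) above
  0.5. A single reference panel (n = 2,000) is reused across
  replicates, as a real analysis reuses one panel for every locus.
- **Recovery**: 200 replicates at 20,000 per cohort; mean `b_SMR`
  within 5% of b_xy = 0.3.

## Known limitations

- LD matrices use complete-case dosage correlation (no phasing); fine
  for the simulated and QC'd panels targeted here, but a panel with
  heavy structured missingness would bias r.
- The delta-method HEIDI variance is first-order; with instruments near
  the eligibility floor (|z| ≈ 3.2) the ratio distribution is skewed
  and the test runs slightly conservative or anticonservative depending
  on LD — the calibration band absorbs this at the default settings.
- Multi-SNP SMR extensions, trans-eQTLs, colocalization posteriors and
  FDR-based gating are out of scope.
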