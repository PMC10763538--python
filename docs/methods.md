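# Methods

This note records the statistical models implemented in `rnaivar`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Expression variance and matched resampling

**Normalization.** Counts are scaled by median-of-ratios size factors
(the median across genes, among genes with a nonzero geometric mean, of the
count-to-geometric-mean ratio per sample). Variance stabilization uses the
negative-binomial delta-method transform

    f(x) = log2( (1 + 2ax + 2·sqrt(ax(1 + ax))) / (4a) ),

the antiderivative of 1/sqrt(v(µ)) for v(µ) = µ + aµ², rescaled to behave
as log2(x) + const for large x. The common dispersion `a` is estimated by
moments from within-strain replicate variation (median of positive
(v − m)/m² over genes with mean normalized count > 5). A plain
log2(x/sf + 1) was considered and rejected: over a realistic expression
range (log2 means spanning ~1–12) its per-gene SD falls steeply with mean
expression, defeating the purpose of the transform; the delta-method form
reduces the SD-versus-mean-rank slope by more than an order of magnitude on
NB simulations. When no dispersion estimate is possible (no replication,
or too few informative genes) the log2(x + 1) fallback is used, which is
exact for the degenerate identical-samples case.

**Strain-wise variance.** Per gene, the between-strain sum of squares from
one-way ANOVA of the transformed values on strain. This is a raw sum of
squares (not divided by df), so with a balanced design it grows with both
effect size and replication — appropriate because all genes share one
design and only relative ranking matters.

**Differential expression.** A one-way ANOVA F-test on the transformed
values with Benjamini–Hochberg adjustment, flagging FDR < 0.1. This is a
deliberate stand-in for a negative-binomial likelihood-ratio test: the
count-model machinery is out of scope here, and the enrichment layer
consumes only boolean flags (externally computed flags can be supplied).
On null NB simulations the stand-in's type-I error is close to nominal
(~5% at α = 0.05; verified in the acceptance suite). Genes with zero
residual variance are flagged degenerate: p = 0 when a strain effect
exists, p = 1 when the gene is constant everywhere.

**Expression matching.** Each focal gene's candidate pool is all non-focal
genes whose mean-expression quantile (average ranks for ties, scaled to
(0, 1]) lies within ±0.005 of the focal gene's. One candidate is drawn
uniformly and independently per slot, so a gene may appear twice in one
null set when pools overlap — the simplest reading of per-slot sampling.
An empty pool raises an error naming the gene.

**Permutation conventions.** The primary permutation p-value is
count/B with ties counted toward the exceeding side, so
`frac_null_below + perm_p = 1` exactly; the (count+1)/(B+1) variant is
always reported alongside (never zero, slightly conservative). The per-set
one-tailed Mann–Whitney test (focal strain-SS greater) uses a vectorized
normal approximation with tie and continuity corrections when both sides
exceed 20, exact enumeration otherwise; the vectorized path is checked
against scipy to 1e-10.

**Hypergeometric enrichment.** P(X ≥ k), exact summation of the pmf in
log space (gammaln + logsumexp), validated against exhaustive draw
enumeration for N ≤ 12 and against scipy's survival function.

## Population-genetic allele fates

Strains are selfing wild isotypes, treated as haploid; heterozygous VCF
calls are demoted to missing with a warning. Variant records are split per
alt allele; the confidence flag is FILTER = PASS.

**Nucleotide diversity.** π = (1/L) Σ_sites (n_s/(n_s−1))(1 − Σ_a p_a²)
with n_s the strains called at the site (missing-aware, site-specific) and
the full gene length L as denominator (monomorphic and unrecorded sites
contribute zero). Sites with fewer than two called strains are skipped.
This equals the average pairwise difference among called strains per site;
the test suite enforces equality with that brute-force oracle to 1e-12,
multiallelic sites included. All variant types count one site each
(an indel is one event regardless of length); a SNP-only mode can be had
by pre-filtering the record table.

**Haplotypes.** Strains with any missing call at the locus are excluded
(and reported). Identical allele vectors collapse to one haplotype;
diversity is Nei's H = (n/(n−1))(1 − Σ p_i²); the Hamming distance matrix
between distinct haplotypes is returned for network construction
(layout/plotting is out of scope).

**Classification rules.** Per (gene, strain), with fractions over gene
length: *pseudogenized* if (≥1 high-confidence high-impact lesion carried
and diverged-or-missing fraction ≥ 1%) or missing fraction > 50%;
otherwise *functionally diverged* if ≥5 carried MODERATE missense records,
diverged fraction ≥ 1%, and no carried high-impact record of any
confidence; otherwise *reference-like*. Missing fraction > 75% sets the
`possibly_missing` flag (such alleles are always in the pseudogenized
branch since 75% > 50%). All five thresholds are overridable via
`Thresholds`. A site both diverged and missing counts once, as diverged.

**Coordinates.** VCF and internal gene spans are 1-based inclusive; BED
masks are 0-based half-open. A gene overlaps a masked interval
[b0, b1) iff its 1-based span intersects [b0+1, b1]; conversions are
centralized in `rnaivar.io` and property-tested by round-trip.

## Penetrance GLMs

Each plate contributes (dead, hatched). The genotype-factor model is fit
as a binomial GLM with logit link; the quasibinomial dispersion is the
Pearson statistic over plates divided by (n_plates − p), and the
coefficient covariance is scaled by it. (The plate — not the embryo — is
the unit for the dispersion df, matching R's `glm(..., quasibinomial)`;
statsmodels' built-in `scale="X2"` uses a different df convention for
two-column endog and is not used.) Every plate is one row regardless of
whether it held a pooled group or a single hermaphrodite.

**Separation.** A genotype whose plates are all-dead or all-hatched would
give infinite logits; it is flagged and given half an embryo of the
opposite outcome, bounding its fitted proportion at 0.5/(N+1) (or the
complement) where N is its total embryo count.

**Contrasts.** All pairwise logit differences with t statistics on the
Pearson-df. The single-step (Tukey-style) adjustment simulates the joint
max-|t| distribution: 20,000 seeded multivariate-t draws from the
estimated contrast correlation (eigen decomposition handles the rank-
deficient contrast family). Adjusted p-values are floored at the raw
p-value. Bonferroni and unadjusted variants are deterministic
alternatives. Family-wise error under a 4-group null is ~5% (verified).

**Complementation patterns.** With estimates for the wild parent P and the
two F1 hybrids H+ (functional *ppw-1*) and HΔ (*ppw-1* deletion), rules
are checked in order: (1) *no rescue* — neither hybrid significantly
exceeds P; (2) *ppw-1-dependent rescue* — H+ > P and H+ > HΔ, both
significant; (3) *ppw-1-dependent suppression* — HΔ > H+ and HΔ > P, both
significant; (4) *ppw-1-independent rescue* — both hybrids exceed P
significantly and do not differ from each other. A layout matching no rule
(e.g. H+ > P but H+ ≈ HΔ with HΔ ≯ P) falls back to *no rescue* with an
ambiguity flag. α defaults to 0.05, the figure-star convention.

**Lifespan model.** Plate-level dead proportion regressed by OLS on
strain, age, strain×age, and worm nested in strain (per-strain worm
dummies, one reference worm per strain, so the design is full rank by
construction); sequential (type I) F tests per term. The proportion
response is modeled directly — heteroscedasticity is accepted as a known
simplification. A per-strain reduced model (age + worm) is available.

## Transcript counts

**Group comparisons** (early embryos, default stage ≤ 4): Welch t-test on
means, variance-ratio F-test (two-sided via doubled tail), Mann–Whitney
(exact for small tie-free samples).

**Excess-mass test.** The statistic is D = max_λ [E_n(2, λ) − E_n(1, λ)]
where E_n(m, λ) is the maximal total excess mass Σ_j (F_n(I_j) − λ|I_j|)
over m disjoint intervals with data-point endpoints; both envelopes are
computed exactly in O(n) per λ by prefix/suffix maxima. The λ grid is 50
log-spaced values spanning the range of a Gaussian-kernel density estimate
evaluated at the data — this makes the statistic exactly invariant to
shifting and (because the grid adapts) to rescaling the data. The null is
calibrated by bootstrap from the unimodal rearrangement of the empirical
CDF: greatest convex minorant left of the KDE mode, least concave majorant
right of it, sampled by inverse transform; p = (1 + #{D* ≥ D})/(B + 1).
The calibration is slightly conservative (≈2% rejection at nominal 5% on
Gaussian nulls) but has essentially full power against well-separated
two-component mixtures at n = 60, B = 500. Constant or near-constant data
are rejected as degenerate. Numeric equality with any particular R
implementation is not claimed.

**ANCOVA** (default stage ≤ 30): nested OLS comparisons
`count ~ stage` → `+ treatment` → `× treatment` give the treatment-effect
and slope-change F tests; ω² = (SS_term − df·MS_err)/(SS_total + MS_err)
from the sequential ANOVA table of the full model, reported unclipped
(small negative values occur under the null). Per-condition slopes and R²
come from separate simple regressions. The sequential table conserves
total SS to 1e-8 by construction.

## Synthetic data

One RNG stream per generator, seeded by (config seed, stage tag), so
adding a stage never perturbs another stage's draws; every generator is a
pure function of its config.

* **Counts** emulate a 5-strain × 3-replicate bulk RNA-seq design over
  18,589 genes (the filtered genome size): per-gene baseline means
  2^U(1, 12), per-(gene, strain) log2-fold effects N(0, sd), NB counts
  with variance µ + aµ² at a = 0.05. The focal set (61 genes) gets
  sd 0.6 vs 0.2 background — a 3× inflation chosen as a clearly
  detectable but not degenerate effect; effect magnitudes in real data are
  unknown, so these are calibration knobs, not estimates.
* **Variant tables** emulate 403 wild isotypes. Each (gene, strain) cell
  draws a scenario (conserved 55%, pseudogenized 15%, functionally
  diverged 15%, possibly-missing 5%, sub-threshold 10%) and the gene's
  records are constructed so the cell satisfies its label's quantitative
  definition with margin (e.g. diverged fractions of 1.2–1.5% against the
  1% threshold, 80% uncalled against the 75% flag). Gene lengths are
  uniform on [500, 5000] bp. Divergence is shared through per-gene
  missense backbones, so linkage structure is crude; the generator makes
  no attempt at realistic site-frequency spectra, recombination, or
  population structure — recovery tests certify the classifier's rule
  branches, not its behavior on real demographies.
* **Plates** draw beta-binomial dead counts with mean p and intra-plate
  correlation ρ (ρ = 0 reduces exactly to binomial); defaults are 8 plates
  × ~150 embryos per genotype, ρ = 0.05, and a rescue-shaped
  (0.05/0.60/0.05) proportion layout. On/off genotypes place one worm per
  plate, on with probability p_on. Lifespan mode emits per-worm,
  per-age-interval counts with a logistic-in-age mean and N(0, 0.3²)
  per-worm logit intercepts.
* **Transcript counts** decline linearly with stage (intercept 130,
  slope −3 per stage, NB dispersion 0.02–0.05), with treated embryos
  knocked down to 8% either wholly (responsive strains) or with mixture
  weight 0.3 (on/off strains). Negative requested means clip at 1 with a
  warning.

What passing tests show: the estimators recover what the generators
planted, at the planted effect sizes, under the stated noise models. Real
data add unmodeled structure (library-composition artifacts, linkage and
demography, plate batch effects, segmentation error in spot counts), so
test results certify correctness of the statistical machinery, not
field performance.

## Problem sizes in the standard runs

The test and acceptance runs use the emulated study dimensions where they
are cheap (18,589 genes × 15 samples for enrichment calibration; 200
self-null replicates at B = 500; 50 power replicates at B = 1,000) and
reduced replicate counts where a single evaluation is expensive
(bootstrap multimodality at B = 200–500 with 60–200 replicates;
403-strain variant tables scaled to 100 strains × 50 genes for the
5,000-cell recovery check). The CLI defaults for `simulate` are similarly
reduced; full-scale runs are a matter of raising the config numbers.

## Known limitations

* The DE stand-in is not a count-model LRT; at very low expression its
  flags and a negative-binomial test's can disagree.
* The excess-mass calibration is conservative at small n; its p-values are
  bounded below by 1/(B+1).
* The variant generator marks missingness via site records, so "missing"
  fractions refer to recorded sites; real coverage-based missingness is
  interval-shaped.
* π uses all record types equally; length-weighted indel handling is not
  implemented.
* The lifespan OLS treats proportions as homoscedastic Gaussian responses.
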