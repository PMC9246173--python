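# Methods

This note documents the models implemented in `locusdissect`, the
synthetic-data generator used to validate them, and the numerical and
design choices that were genuinely open.

## Locus catalogue

A locus table is a TSV of GWAS summary rows: rsid, `chrom:pos` (1-based),
effect allele a1, other allele a2, log-odds `beta` per a1 copy, `se`, and
`pvalue`. P values are accepted in plain or typeset scientific notation
(`1.25e-24`, `1.25 x 10-24`, unicode minus). The lead SNP is the row with
the smallest P, ties broken by larger |beta|/se then rsid; the locus span
is `max(pos) − min(pos) + 1` (inclusive). LD is the Pearson correlation
of dosage vectors (composite LD — appropriate for unphased dosages),
pairwise-complete with a 30-pair minimum; monomorphic variants yield NaN
with a warning, never a silent zero. Wald P values `2Φ(−|β/se|)` are
evaluated in log space; below double precision the linear-scale value is
floored at the smallest positive double and `log_wald_p` is provided for
exact work. SNP feature annotation uses 1-based inclusive intervals with
priority coding-exon > UTR > intron; BED's 0-based half-open convention
appears only in the accessibility module, where the conversion is
centralized and boundary-tested.

## Fine-mapping

Two summary-statistics models:

* **Single-causal ABF.** Per variant, Wakefield's approximate Bayes
  factor with prior effect variance `W` (default 0.04, i.e. prior SD 0.2
  on the log-odds scale, conventional for binary traits). PIPs are
  `ABF_i / Σ_j ABF_j` via log-sum-exp; the credible set is the smallest
  PIP-descending prefix reaching the coverage level (ties by rsid).
* **Configuration enumeration.** For a configuration C of causal
  variants, the z-scores are modelled as `z ~ N(0, R + R_C S R_C′)` with
  `S = diag(s²)` on the standardized scale (default s² = 25, prior z-SD
  5, appropriate for genome-wide-significant loci). The Bayes factor
  against the null reduces, by the determinant lemma and Woodbury
  identity, to |C|×|C| operations:
  `log BF = −½ log det(I + S R_CC) + ½ z_C′(S⁻¹ + R_CC)⁻¹ z_C`,
  so exhaustive enumeration to k_max = 2 over 36 variants costs only
  ~700 small solves. The configuration prior is
  `p^|C|(1−p)^(m−|C|)` with p = 1/m by default; the posterior yields
  PIPs and P(k causal variants). A ridge of 1e-4 is added to the LD
  diagonal; a failed Cholesky falls back to eigenvalue clipping at 1e-6.
  With k_max = 1, diagonal LD and s² = W/V the conditional PIPs equal the
  ABF model's (tested).

On the packaged 36-SNP catalogue the single-causal model concentrates
essentially all posterior mass on the lead SNP; the credible set is a
singleton. The enumeration guard refuses more than 64 variants.

## cis-eQTL mapping

Sample QC drops libraries under 1,000,000 reads first; gene QC then keeps
genes with CPM > 1 in at least two surviving samples. Raw counts are
transformed as log2(CPM + 1). The cis window is |variant − TSS| ≤ 1 Mb,
inclusive, same chromosome. Each (variant, gene) pair is fit by OLS of
expression on dosage plus optional covariates; the slope sign convention
is positive = effect allele increases expression. P values use the t
distribution with n − p − 2 df. BH-FDR is applied across all tested
pairs within one tissue — the family choice is a documented decision
(configurable by subsetting `pairs`); significance is FDR ≤ 0.05.
Constant dosages and rank-deficient designs (e.g. a covariate collinear
with the dosage) are skipped and logged, never reported as numbers. A
vectorized path handles the covariate-free complete-data case; the
general path fits pair by pair. Expression–trait association is Pearson
correlation with the exact t transform, pairwise-complete.

## Mendelian randomization

Exposure (eQTL) and outcome (GWAS) summaries are harmonized to the same
effect allele: swapped alleles flip the outcome beta, strand-ambiguous
A/T and C/G variants are dropped with a warning, irreconcilable pairs
are errors. The Wald ratio `b_xy = b_zy / b_zx` carries the delta-method
variance `se_zy²/b_zx² + b_zy² se_zx²/b_zx⁴`; instruments below z ≥ 3
exposure strength are refused to prevent ratio blow-up. Fixed-effect IVW
(not random-effects — cis-MR with few instruments) combines ratios with
weights 1/se²; a single instrument reduces exactly to the ratio.

**HEIDI.** The top instrument is the largest exposure χ²; eligible
instruments need exposure z² ≥ 10 and LD r² to the top in [0.05, 0.9].
For each, `d_i = b_xy(i) − b_xy(top)`; the covariance of d propagates
`cor(z_i, z_j) = r_ij` on both the exposure and outcome sides through
the delta method. `T = Σ d_i²/Var(d_i)` is referred to the weighted-χ²
mixture whose weights are the eigenvalues of the correlation matrix of
the standardized d, using the Satterthwaite two-moment approximation
(scale = Σλ²/Σλ, df = (Σλ)²/Σλ²) — chosen over saddlepoint methods as
monotone, desk-scale, and exactly χ² in the diagonal-LD, noise-free-top
limit (tested against that limit). Fewer than three eligible instruments
returns "not evaluated", not a P value. Small P means the per-variant
ratios disagree — linkage with a distinct causal variant rather than one
shared signal.

Calibration, measured by the packaged experiments: type-I error 0.046 at
α = 0.05 over 500 single-shared-causal replicates (exchangeable LD
r = 0.6, 20 variants, exposure non-centrality 10); power 0.86 over 100
replicates when exposure and outcome are driven by distinct variants in
the same LD block.

A vectorized Newton–Raphson logistic scan (`logistic_assoc`) produces
per-variant log-odds summaries for binary outcomes; it matches
statsmodels' Logit to 1e-6 (tested) and fits all variants simultaneously.

## Co-expression networks and key drivers

Unsigned adjacency `a_ij = |cor|^β` with soft power β = 6 (the WGCNA
convention for unsigned networks); topological overlap
`TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)` with
self-adjacency excluded from connectivity. Modules come from
average-linkage clustering of 1 − TOM with a **static** height cut
(default 0.75) — a documented simplification of dynamic tree cut;
clusters under 10 nodes go to the grey pool. Module eigengenes are first
principal components, sign-oriented to correlate positively with their
members and scaled to unit variance; module–trait association reuses the
Pearson machinery. Cross-tissue networks concatenate matrices on shared
samples with (gene, tissue) nodes. Key drivers are nodes whose
depth-d neighborhood (graph binarized at the top 1% of edge weights) is
enriched for a module's members by the hypergeometric upper tail, BH-FDR
across nodes per module, flagged at FDR ≤ 0.05 with ≥ 5 neighbors. This
neighborhood-enrichment formulation replaces Bayesian-network key-driver
machinery; regulatory-direction inference (tree-ensemble methods) is out
of scope, so the graph is undirected.

## Accessibility linkage

Peaks are 0-based half-open; a SNP at 1-based p occupies the point p − 1.
Peak-to-gene links are Pearson correlations across ≥ 20 pseudo-bulk
groups for pairs with peak-center-to-TSS distance ≤ 250 kb (strand-aware
TSS from the annotation), BH-FDR over tested pairs, retained at
|r| ≥ 0.45 and FDR ≤ 1e-4 — defaults following the conventions of
single-cell accessibility toolkits, configurable. Zero-variance peaks or
genes are skipped and logged. SNP→gene linkage composes containment with
retained links, deduplicating genes by the strongest |r|. Interval
containment uses an interval tree and is tested against a brute-force
all-pairs scan.

## Synthetic data generator

The generator emulates the statistical structure of a multi-tissue
genetics-of-gene-expression study paired with a large case-control GWAS:

* **Genotypes.** Two independent haplotypes per sample are thresholded
  from a latent Gaussian with exchangeable within-block correlation, at
  the quantile matching each variant's MAF (drawn uniformly from
  (0.1, 0.4), shared within a block — with unequal frequencies two
  binary variants cannot reach high dosage correlation). Thresholding
  attenuates correlation, so the latent value is calibrated by solving
  the bivariate-normal (tetrachoric) relation so the realized **dosage**
  correlation matches `within_block_r`; a target of 0.9 yields r² ≈ 0.81
  between block-mates. Defaults: 36 variants in six blocks of six at
  r = 0.5, echoing a tight GWAS locus.
* **Expression.** Per tissue, `n_modules` latent factors; module genes
  are `ℓ·f + √(1−ℓ²)·ε` with loading ℓ = 0.9. The default loading is
  deliberately strong: with the static cut at 0.75 and β = 6, modules
  with within-correlation below ~0.8 are not separable by construction,
  and ℓ = 0.9 (correlation 0.81) is the weakest round value the
  clustering defaults can recover. The target gene adds
  `eqtl_beta × dosage(causal variant)` — in arterial tissues only — on
  top of its unit-variance factor-plus-noise term (default
  eqtl_beta = 0.5 expression-SD per allele; the source studies do not
  state the underlying effect magnitudes, so this is configuration, not
  a claim).
* **Outcome and traits.** `y ~ Bernoulli(logistic(α + mediated_beta·x))`
  with x the arterial target-gene expression and α = −1 (prevalence
  ≈ 0.27, a case-enriched cohort); default mediated_beta = 0.4 log-odds
  per expression SD, so the marginal per-allele log-OR is ≈ 0.2 (the
  product, minus a small logistic marginalization attenuation). A
  logistic outcome was chosen over a liability threshold to match the
  log-odds scale of GWAS betas. The trait table plants one column
  correlated with target expression at r = 0.3 plus pure-noise columns.
* **Accessibility.** One peak containing the causal variant co-varies
  with target-gene group-level expression at r = 0.6 across 100
  pseudo-bulk groups; everything else is independent noise.
* **Layout.** A deterministic annotation places the variants in a ~28 kb
  window on one chromosome, a decoy gene physically spanning the SNPs
  (final intron + 3'UTR intervals), and the target gene's TSS ~120 kb
  away — cis, but not hosting any variant.

All randomness flows from one seeded `numpy.random.Generator`; identical
configs give bit-identical output. What the generator does **not**
emulate: read-level noise, population structure and relatedness,
haplotype phasing, count overdispersion, hidden expression confounders,
and trans effects. Passing tests therefore demonstrate correctness of
the estimators under the assumed generative laws, not robustness to
every artefact of real cohort data.

## Replicated experiments and problem sizes

The packaged experiments (shared by the test suite and
`scripts/acceptance.py`) use these sizes, chosen to make each check
statistically informative at desk scale:

* **MR recovery** — 100 studies, n_eqtl = 500, n_gwas = 20,000,
  eqtl_beta = 0.5, mediated_beta = 0.4, twelve **independent**
  instruments. Independence is deliberate: selecting the strongest eQTL
  among correlated LD proxies inflates the exposure effect (winner's
  curse) and visibly degrades CI coverage, so the calibration experiment
  follows standard two-sample-MR practice of LD-independent instruments;
  the pipeline itself LD-prunes at r² < 0.1 for the same reason, and
  top-SNP selection within an LD block remains a known source of mild
  downward bias in single-locus MR.
* **HEIDI calibration** — 500 null / 100 alternative replicates simulated
  at the summary-statistic level (`z ~ N(Rλ, R)`), which is exact for
  these tests and cheap.
* **Fine-mapping recovery** — 100 loci of 36 variants (blocks r = 0.5),
  causal non-centrality z = 8.
* **eQTL null FDR** — 100 replicates of 200 null genes × 36 variants at
  n = 100; the per-replicate false-discovery proportion is averaged.
  Under the global null this proportion is nearly Bernoulli(α), so the
  100-replicate mean carries Monte-Carlo noise of about ±0.02.
* **End-to-end ranking** — 100 pipeline runs at n_eqtl = 300,
  n_gwas = 8,000, 44 genes: small enough to run the whole pipeline a
  hundred times in tens of seconds, large enough that every evidence
  stage is well-powered.

## Known limitations

* The static-cut module detection requires strongly separated modules;
  dynamic tree cut would recover weaker structure.
* Fixed-effect IVW assumes instrument independence; the pipeline's LD
  pruning enforces this only approximately (r² < 0.1).
* The Satterthwaite tail approximation in HEIDI is accurate near
  conventional α but not deep in the tail.
* The composite gene score is an unweighted evidence count with a
  direction-concordance bonus; it is intentionally transparent rather
  than optimal, and weights are configurable in code.
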