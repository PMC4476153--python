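# Methods

## The quantity being measured

For each gene, tissue and sex, the pipeline asks how far current human
expression has moved from the expression of the human–chimp common ancestor,
in units of the combined uncertainty:

    Z = (E_c − E_a) / √(V_c + V_a)

`E_c` and `V_c` are the mean and unbiased sample variance of normalized
(RPKM-like) expression across human replicates; `E_a` and `V_a` are the
posterior mean and variance of the ancestral state under a Brownian-motion
(BM) trait model on a fixed five-primate phylogeny (human, chimp, gorilla,
orangutan, macaque; branch lengths in millions of years, human–chimp split
at 6.4 Ma). Within every tissue × sex the Z distribution is recentred to
median zero (`Z_mod = Z − M`), encoding the assumption that the
transcriptome neither grows nor shrinks on net; all downstream statistics
are rank- or sign-based, so the correction changes nothing but the sign
labels of genes near the median.

Everything else in the package is machinery for asking whether `Z_mod` (or a
derived score such as the sex-bias SMA residual) is structured along the
genome: neighbor correlations, sign-run statistics, cluster spectra,
distance-decay correlograms, cross-tissue concertedness, interval overlaps
and scalar-track correlations — each with a randomization null.

## Ancestral estimation

With `x` the five species means, tip covariance `σ²C` (where `C[i,j]` is the
MRCA depth of tips i, j) and ancestor node `a`:

* GLS root mean: `μ̂ = (1ᵀC⁻¹x)/(1ᵀC⁻¹1)`; ML rate `σ̂² = Q/n` with
  `Q = (x−μ̂1)ᵀC⁻¹(x−μ̂1)` (REML `Q/(n−1)` by flag).
* `ancestral_posterior` is the textbook conditional Gaussian at a *fixed*
  `(μ, σ²)`: `E_a = μ + C_at C_tt⁻¹ (x − μ1)`,
  `V_a = σ²(c_aa − C_at C_tt⁻¹ C_ta)`.
* The pipeline's default (`AncestralModel.estimate(..., uncertainty=
  "marginal")`) integrates `μ` and `σ²` out under flat priors on
  `(μ, log σ²)`. The node state is then a scaled Student-t with `n−1`
  degrees of freedom, location equal to the plug-in `E_a`, and variance

      V_a = Q·s̃/(n−3),   s̃ = schur + (1 − C_atC_tt⁻¹1)²/(1ᵀC_tt⁻¹1).

  This is a deliberate design choice: with only five tips the rate is poorly
  determined, and the plug-in Schur variance produces ~86–88% coverage of
  1.96·√V_a intervals (a t₄ pivot mistaken for a normal). The marginal
  variance is also exactly what the variance of a long MCMC posterior sample
  measures, so the analytic and MCMC routes estimate the same quantity; the
  package verifies ~95% coverage against simulated truth.
* The MCMC (`mcmc_ancestral`) is a seed-reproducible random-walk Metropolis
  sampler over `(μ, log σ², x_a)` with flat priors, component-wise proposals
  adapted toward 44% acceptance during the discarded portion of the chain.
  By default the final 10% of samples are retained and summarized; the
  retained fraction is a pure Monte Carlo precision knob (chains initialize
  at the analytic estimates, so burn-in is immediate), and precision-hungry
  comparisons retain more. A split-half mean check (difference < 0.1
  posterior SD) is logged, not enforced.

The analysis is performed on the scale the expression files provide, as a
practitioner would run a BayesTraits-style continuous model on the published
RPKM matrix. The parameter-recovery experiment instead log-transforms the
species means, because the synthetic generator evolves log-expression — on
that scale generative and inference models coincide and coverage is a
meaningful calibration check (see below).

## Z-score edge rules

* Degenerate denominator (`V_c + V_a = 0`) with equal means gives Z = 0;
  with unequal means a signed-infinity sentinel that is excluded from every
  rank statistic.
* "Zero owing to lack of expression" is operationalized as `E_c = 0` and
  `E_a ≤ 0` (`zero_flag`); such genes are excluded by default and retained
  under a switch.
* Fold change `E_c/E_a` is undefined (NaN, excluded) when `E_a ≤ 0`.
* Single-replicate groups (the one-sample female data) use `V_c = 0` with a
  flag; V_a then carries the whole denominator.
* Expression-profile measures floor tissues below 2 RPKM to zero before
  computing breadth, mean/peak rate and tau. In
  `τ = Σⱼ(1 − log eⱼ/log e_max)/(n−1)` a zeroed tissue contributes its limit
  term 1 (it is maximally "off"); the log base cancels; a gene expressed
  nowhere has breadth 0 and undefined tau.

## Genome conventions

Gene tables are 1-based inclusive; BED is 0-based half-open, converted
centrally. "Downstream" means increasing published-strand coordinate
regardless of gene orientation; the nearest downstream neighbor is the gene
with the smallest start strictly greater than the focal start, ties broken
deterministically by (end, id). Two distance conventions are supported
(body gap, default; start-to-start), both with a 100 kb default radius —
the empirically motivated scale of short-range chromatin "ripple" effects.
Touching genes (gap 0) do not overlap; overlap means the inclusive spans
intersect. Window-mode analyses drop focal genes that overlap an adjacent
gene and keep overlapping non-focal neighbors; nearest-neighbor modes
analyze non-overlapping and overlapping pairs as separate strata.

## Randomization machinery

* Sign runs: zeros are removed; an edge is an adjacent unequal pair within a
  chromosome. The null permutes signs within each chromosome (preserving
  per-chromosome +/− counts exactly); the test is one-tailed for an edge
  deficit. All Monte Carlo P values use the unbiased estimator
  `P = (N+1)/(M+1)`.
* Cluster spectra count maximal same-sign runs by size, with per-size
  one-tailed ("as many or more") empirical P and null quartiles.
* Distance decay pairs each focal gene with the nearest downstream scored
  gene at body distance ≥ x over a grid of x; the envelope is mean ± 1.96 SD
  of the per-x rho over shuffles of the scores across loci (genome-wide by
  default; per-chromosome by flag).
* Subset Monte Carlos draw equal-size random subsets of the pair pool and
  count draws with rho ≥ observed (one-tailed "greater").
* Spearman uses average ranks with the two-sided t approximation for n > 10
  and an exact permutation P below; Mann–Whitney uses the tie-corrected
  normal approximation. Bonferroni families are the rows of the table being
  reported.
* The Z-sum test builds the 2k+1-category histogram of summed per-tissue
  signs against a null that permutes each tissue's sign column independently
  (preserving per-tissue totals). Cells with expectation < 5 are pooled
  toward zero. Both an analytic chi-square P (df = cells − 1) and an
  empirical P (observed statistic vs the same statistic in each
  randomization) are reported; the empirical P is the calibrated one and is
  what the tests assert on.
* Concerted-gene clusters (|Z sum| = tissue count, same sign, adjacent, size
  ≥ 2) are broken by any intervening non-concerted gene and at chromosome
  boundaries; positions are permuted within chromosomes. The default
  M = 10,000 makes the smallest attainable P 9.999×10⁻⁵.
* The H3K4me3-style overlap comparison is the *two-cell* chi-square: with
  N± genes of each sign and O± of them overlapping ≥ 1 peak,
  `E± = N±(O₊+O₋)/(N₊+N₋)` and `χ² = Σ(O−E)²/E` over the two overlap cells,
  df = 1. Overlap counts may be fractional (averages over replicate peak
  sets). This form — not the four-cell 2×2 — reproduces the published
  worked values, which the acceptance suite checks.
* TSU (tissue-specific upregulated) genes have Z > 1 in exactly one tissue
  and Z ≤ 0 (strict) or Z < 1 (relaxed) elsewhere. The neighbor test
  compares, per tissue, TSU genes whose nearest neighbor (closer flank,
  split at 100 kb) has Z > 0 in the focal tissue against the genome-wide
  Z > 0 proportion (zeros excluded); contributions are summed with
  df = tissues − 1, and per-tissue Ps are combined by Fisher's method
  (df = 2k).

## Sex bias

Within each tissue the female Z is regressed on the mean male Z by standard
major axis: slope `sign(r)·SD(y)/SD(x)` through the centroid. The sex-bias
change score is the vertical deviation standardized to unit SD; the signed
orthogonal distance differs only by the constant `√(1+slope²)`, so
standardized values and all rank statistics are identical between the two
readings (a flag exposes the raw orthogonal residual). Residuals are
standardized per tissue. Genes with a zero flag in either sex are excluded
by default with a retain switch. X-chromosome tests: Mann–Whitney on
|standardized residual| X vs autosomes, a 2×2 chi-square of X membership ×
top-⌈5%⌉ modulus membership, and per-tissue X vs autosome median-Z
Mann–Whitneys.

## The synthetic generator

`simulate.SimConfig` defaults emulate the data regime of the original
five-primate, six-tissue expression study this pipeline targets: 13,027
genes on 23 chromosomes (last labelled X), six tissues, males in all six
and females in four (no female liver/testis), three male replicates and a
single female replicate, exponential gene lengths (mean 30 kb) and
intergenic gaps (mean 60 kb) so an appreciable fraction of neighbors fall
within 100 kb, and 5% of adjacent pairs forced to overlap.

Expression evolves on a latent natural-log scale: per gene × tissue the
root value is `base_g + tissue_offset` (log-normal expression with a median
around 20 RPKM and realistic tissue specificity), BM runs along the tree at
0.01 latent units²/My (≈0.5 SD root-to-human, i.e. mostly < 2-fold drift),
and the human tip additionally receives a block shift: contiguous 10-gene
blocks (never spanning chromosomes) are shifted with probability 0.15 with
half-normal magnitude (SD 0.5); a configurable fraction of shifted blocks
is concerted (one sign across all tissues) and another fraction receives a
sex-differential shift (males +δ/2, females −δ/2). Replicates add latent
Gaussian noise (SD 0.2) before exponentiation, so emitted values are
positive while the evolutionary model stays Gaussian. Where the emulated
study fixes no generative magnitudes, these defaults were chosen once as
plausible for primate expression divergence and are documented free
parameters, not fitted quantities.

Annotations are coupled to the truth with a signed strength in [−1, 1]:
LAD-like intervals cover negatively shifted blocks, peak-like (and
gained-peak) intervals cover positively shifted genes, depleted-peak
intervals the opposite, and the hmC-/mC-like scalar tracks are ±coupling ×
standardized shift plus noise. Coupling 0 makes every membership
independent of the truth, which the tests verify.

What the generator does *not* emulate: read-level sampling noise,
GC/amplification bias (the Z construction argues these cancel between human
and chimp), isoform structure, expression-level-dependent variance beyond
the log-normal form, and real chromosomal gene-density heterogeneity.
Passing tests therefore demonstrate that the statistics recover planted
structure of the assumed form at realistic scales — not that the biological
conclusions of any particular dataset are correct.

## Problem sizes and calibration results

The test suite and analysis drivers scale the simulations to desk size,
chosen as the smallest sizes at which the checks are statistically
meaningful:

* Ancestral recovery: 500 shift-free genes, single noise-free replicate,
  log-scale inference. Mean error ≈ 0.002 against a 0.05·SD bound; 95.2%
  coverage of 1.96·√V_a intervals; MCMC (200k chain, 24 genes) within
  0.021·√V_a of the closed form.
* Type-I calibration: 200 seeds of 600-gene null studies; neighbor
  correlation, run-edge and Z-sum tests each fire at ~5% (band 2.5–7.5%).
* Power: 100 seeds of 1,500-gene studies with 10-gene blocks, shift
  probability 0.5 and shift SD 1.5 ("strong" shifts ≈ 4.5-fold expression
  changes): neighbor rho > 0 at P < 0.001 and a size-≥5 cluster excess
  beyond the null 97.5th percentile in ≥ 95 seeds each; the decay profile
  leaves the envelope at 10 kb and re-enters by 5 Mb, bracketing the
  planted ~1 Mb block span.
* The analysis drivers use one 4,000-gene, 8-chromosome study (seed 2024).

## Known limitations

* The BM model is non-directional with no Ornstein–Uhlenbeck or trend
  variant; branch lengths are taken as given.
* The marginal V_a requires ≥ 4 tips; with fewer, only the conditional form
  is defined.
* `nearest downstream at minimum distance x` uses a start-sorted search and
  can miss pathological nested-gene geometries; at realistic overlap rates
  this does not occur in the test fixtures.
* The analytic Spearman P is a t approximation for n > 10; exact permutation
  below that is O(n!) and capped at n = 10.
* Chromosome-scale contrasts (X vs autosomes) inherit block-level
  correlation when scores are spatially clustered; their P values should be
  read with that reduced effective sample size in mind.
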