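# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions.

## Coordinate and format conventions

All internal arithmetic is 0-based half-open.  BED input/output is 0-based
half-open; GTF is 1-based closed and converted on read/write.  The TSS is
the 5′ end of the strand (smallest start on `+`, last covered base on
`-`).  "Within *w* kb of the TSS" is measured from the nearest TE edge to
the TSS point, boundary inclusive, strand-symmetric — the convention of
windowBed, the standard tool for this operation; the alternative
(midpoint, strand-aware) readings are not implemented.  The upstream
promoter is the strand-aware half-open interval covering `promoter_kb` kb
upstream of the longest transcript's 5′ end, truncated at position 0; a TE
counts as present on ≥ 1 bp overlap.  Identical TE intervals with distinct
ids give distinct pairings.

## Relative coexpression

For tissues *a, b* and gene set *S*, `corr(S; a, b)` is the Pearson
correlation across genes in *S* between the two tissues' profiles
(per-gene mean of √TPM over each tissue's samples).  The square-root
transform stabilises the variance of TPM before correlating; Pearson on
this scale is the natural reading of "transform, then correlate".  The
statistic per pair is

    ratio = corr(TE+; a, b) / corr(TE−; a, b)

computed after an expressed-gene filter (mean TPM over all samples ≥ 1 by
default; the threshold is exposed).  The null resamples, without
replacement, |TE+|-sized gene sets from the TE-absent expressed pool and
recomputes the ratio with the draw as numerator and the remaining
TE-absent genes as denominator — keeping numerator and denominator pools
disjoint exactly as in the observed statistic.  The resampled index sets
are drawn once, before iterating tissue pairs, so results do not depend on
pair order.  The empirical p uses the add-one rule
`p = (1 + #{null ≤ observed}) / (B + 1)` with the "lower" tail fixed a
priori (the hypothesis is *less* coexpression); `higher` and `two-sided`
alternatives are available.  An exhaustive mode enumerates every subset
(for small instances) and is the oracle the Monte-Carlo mode is tested
against.  The per-pair summary `odds_ratio = (1 − p)/p` is the simplest
nonparametric odds of the effect; it is a reporting convention, not an
estimate of a population odds ratio.  Tissue pairs are reported
individually without multiplicity correction (a Benjamini–Hochberg option
exists but is off by default).  Degenerate pairs (zero-variance profile,
zero denominator correlation) are flagged `valid=False` rather than
computed.

## Enriched-gene calling

TPM from counts is `rate_g = count_g / eff_len_g`, scaled to sum 1e6 per
sample.  Ortholog restriction keeps resolvable 1-to-1 pairs only and
re-normalises TPM over the retained set (per-sample sums return to 1e6).

**TMM.**  For sample *j* against reference *r* (auto-reference: sample
whose upper-quartile expression is closest to the mean upper quartile),
over genes positive in both: `M = log2 x_j − log2 x_r`,
`A = ½(log2 x_j + log2 x_r)`.  The most extreme 30 % of M and 5 % of A are
trimmed from each tail (the canonical trim constants) and the factor is
`2^(Σ wM / Σ w)` with delta-method weights
`w⁻¹ = (N_j − x_j)/(N_j x_j) + (N_r − x_r)/(N_r x_r)`, N = sample total;
factors are rescaled to geometric mean 1.  M is computed on the values as
given — the pipeline feeds TPM, which is already on a common library
scale, so the factors capture composition and residual scale differences
(and a pure 2× scaling of one sample is recovered as a factor ratio of 2).
Fewer than 2 genes surviving trimming is an error; fewer than 10 logs a
warning (small fixtures are legitimate, but factors are then unstable).

**Rank product.**  For groups A vs B, every sample combination (a, b)
ranks genes by fold change in the tested direction (rank 1 = strongest,
ties averaged; fold changes are `log2((x_a + ε)/(x_b + ε))`, ε = 1e-8
guarding zeros).  `RP_g` is the geometric mean of the ranks.  The pfp is
estimated by permutations that shuffle each sample's gene labels
independently: `pfp(g) = E[#null RP ≤ RP_g] / position(g)`, made monotone
along the RP ordering by a cumulative maximum.  This permutation scheme
preserves the per-sample marginal distributions; because permuted rows mix
unrelated genes, the null's cross-combination correlation is somewhat
stronger than the observed background's, making the pfp mildly
conservative — precision in the recovery experiments is correspondingly
near 1 while recall carries the cost.

**Calling.**  A gene is focal-tissue-enriched when it is significant
(direction "up", pfp ≤ 0.15) in *every* comparison: focal vs each other
tissue of species A, and species-A focal vs species-B focal.  The
per-comparison-then-intersect design (rather than one pooled test) is the
literal composition of the per-contrast differential expression analyses.
TMM is computed once across all pooled, ortholog-restricted samples of
both species, then comparisons run on the normalised matrix.

## Binomial TE enrichment

The unit is the gene: the indicator "has ≥ 1 TE in the promoter window"
avoids the ill-posed choice of an n for per-occurrence counts (raw counts
are exposed alongside).  With `p0 = n_with_TE / n_genes` over the
universe, `p = P(X ≥ k)`, `X ~ Binomial(n_enriched, p0)`, evaluated by
exact log-space summation of the tail (no normal approximation); the
one-sided upper tail is the default since the hypothesis is
over-representation (a two-sided option exists).  The fold
`(k/n)/p0` is reported alongside.

## PWM scanning

TFs are first filtered to those with minimum TPM ≥ 10 across **all**
samples supplied (boundary inclusive).  Log-odds are in bits:
`score(i, b) = log2(((p_ib + c·bg_b)/(1 + c))/bg_b)` with
background-proportional pseudocount c = 0.01 (avoids −∞ on zero cells;
in the limit c → 0 a certain base over uniform background scores 2 bits).
A window's score is the sum over positions; both strands are scanned
(minus strand = scoring the reverse-complement window) and hits at or
above the threshold (default 8 bits) are reported with forward-sequence
offsets.  The threshold's scale is convention-dependent (log base and
smoothing differ between motif databases), so it is an exposed parameter.
Windows containing N are skipped.  The 5′ junction window of a TE is
`flank_bp` of flanking DNA plus the first `flank_bp` of the element,
reverse-complemented for minus-strand elements.

## Synthetic-data generator

Log-scale model for gene g, sample s of tissue t:

    log x_gs = m0 + τ_t + f_g + δ_g·[t = focal, g planted] + ε_gs

with gene latent `f_g ~ N(0, σ_f²)` shared by all samples and both
species, sample noise `ε ~ N(0, noise_sd²)`, small tissue offsets
`τ_t ~ N(0, 0.2²)`, and `σ_f² = base_corr/(1 − base_corr)·noise_sd²` so
the cross-tissue correlation of per-sample log expression is `base_corr`.
Values are exponentiated and rescaled to TPM per sample.  A log-normal
model was chosen over negative binomial counts because every downstream
statistic consumes TPM, not counts; count-level overdispersion, batch and
sex covariates, and read-level simulation are deliberately out of scope.

**Planted effect.**  Truth genes (a `te_fraction` of all genes) receive a
strictly positive up-shift in the focal tissue only:

    δ_g = effect_size · noise_sd · (1.1 + L_g),   L_g ~ LogNormal, E L = 0.35, SD L = 1.0

`effect_size` parametrises the *standard deviation* of the planted
divergence: `SD(δ) = effect_size · noise_sd` exactly.  The shape is a
deliberate compromise between the two consumers of the effect: the
coexpression test detects only the gene-to-gene *spread* of δ (a constant
shift leaves Pearson correlations unchanged), while rank-product recovery
requires every planted gene to be genuinely up with a fold change above
the detection margin — hence the firm floor at 1.1× scale and the heavy
right tail carrying the spread.  The implied mean group shift is
≈ 1.45 × effect_size × noise_sd (≈ 1.4 natural-log units at the default
effect_size 2, noise_sd 0.5), which the generator tests assert via a
difference-in-differences on the emitted matrix (the TPM renormalisation
subtracts a per-sample constant that plain group means would absorb).

**TE placement.**  One TE of `te_length` bp (default 366) is planted with
its nearest edge uniformly within `window_kb` of each truth gene's TSS
(upstream or downstream), plus an equal number of background TEs placed
uniformly; genes are spaced widely enough that TSS windows are disjoint,
so the truth set is exactly recoverable by the association module
(verified by a closing-the-loop test), while background TEs create
realistic incidental associations.  Species B shares the gene latents
(orthologs are correlated across species) but never the planted effect —
the divergence is species-A-specific by construction.  Coordinates live on
a single chromosome; multiple chromosomes are a naming convention away but
not needed by any consumer.

**What passing tests do and do not show.**  The generator produces
well-behaved log-normal TPM with exchangeable genes under the null, so the
calibration results (uniform p-values, nominal type-I error) demonstrate
the *statistics* are correctly implemented — not that real RNA-seq, with
its count noise, mappability artefacts, batch structure and correlated
gene programs, would behave as cleanly.  Power numbers (focal-pattern
recovery, precision/recall ≥ 0.8) are statements about the planted-effect
regime documented here, not about any particular genome.

## Standard study conditions

* Coexpression experiments: 5 tissues, 1 sample per tissue (tissue
  profiles then reduce to single samples; correlations are across genes),
  base_corr 0.7, noise_sd 0.5.  Null calibration: 200 bundles of 1,000
  genes, 500 resamples, one fixed tissue pair per bundle.  Power: 50
  bundles of 2,000 genes, te_fraction 0.1, effect_size 2, 500 resamples
  (the production default remains 5,000; 500 keeps replicated experiments
  fast and was verified to give the same successes as 5,000).
* Enriched-gene experiments: 5 tissues × 8 samples in both species, 1,000
  genes, 50 planted (te_fraction 0.05), rank product with 100
  permutations, FDR 0.15.  Eight replicates per group reflects that the
  rank product's per-combination ranks do not sharpen with replication —
  only the permutation null concentrates — so replicate count is the
  design's main power knob.
* Binomial experiments: 1,000 genes, 50 planted with TEs at the TSS,
  20-kb upstream promoter indicator.

## Numerical notes and limitations

* Every random operation takes an explicit seed (`numpy` Generator);
  replicate seeds derive from a base seed by a stable hash, so experiments
  are reproducible and replicates independent.  Reports are JSON with
  sorted keys; repeated runs are byte-identical.
* Empirical p-values are bounded below by 1/(B+1); odds ratios are
  correspondingly capped at B.
* Pearson correlations on √TPM are dominated by high-expression genes;
  this matches the transform's definition but means small gene sets give
  noisy ratios (the 3-gene minimum is a hard floor, not a recommendation).
* The binomial background treats genes as exchangeable; GC- or
  length-matched backgrounds are a known refinement outside scope.
* `tissue_enriched_genes` assumes both species have samples of the focal
  tissue and at least one other tissue in species A.
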