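# Methods

This note documents the models, estimators and numerical choices behind
`pleiomix`, what the synthetic generator does and does not emulate, and the
known limitations.

## Generative model (synthetic paired GWAS)

Each of M template variants independently belongs to one of four components —
null, A-only, B-only, shared — with probabilities (π₀, π₁, π₂, π₁₂).
Causal effects are drawn per component: trait-specific effects
β ~ N(0, σ_β²); in the shared component (β_A, β_B) is bivariate normal with
correlation ρ_β. Observed z-scores follow the standard summary-statistic
sampling model per LD block with signed correlation matrix R:

    z_A = √n_A · R β_A + ε_A,   Cov(ε_A) = σ₀A² R,
    Cov(ε_A, ε_B) = ρ₀ σ₀A σ₀B R.

Noise covariance proportional to R (not the identity) matches the sampling
distribution of marginal association z-scores, so the mixture model's
assumptions hold exactly in simulation. σ₀² > 1 models residual inflation and
ρ₀ models sample overlap between the two GWAS. A replication cohort reuses
β_A with a new sample size and a noise stream independent of discovery.

The LD reference is block diagonal with AR(1) decay, r(i,j) = decay^|i−j|,
positive semi-definite by construction, variants spaced 10 kb within blocks
and blocks 1 Mb apart across chromosomes 1–22. The harness default is blocks
of 20 variants at decay 0.6 (adjacent r² = 0.36, below the 0.05 partner
threshold within three positions), a pattern typical of common variants at
this spacing. Defaults for the study conditions are M = 30,000,
n = 50,000 per GWAS, σ_β² = 5·10⁻⁴ (so n·σ_β² = 25, a well-powered GWAS;
h² ≈ 0.15 at total polygenicity 0.01), and π components of 0.005.

What the generator does **not** emulate: minor-allele-frequency–dependent
effect sizes, genotype-level sampling, long-range LD beyond the block span,
per-variant sample-size variation (the reader supports it; the generator
holds N constant per trait), and sex chromosomes. Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to every artefact of real GWAS.

Seeding: a single global seed expands into independent per-stage streams
(effects, z-scores, replication) via `numpy.random.SeedSequence` spawn keys,
so each stage is reproducible in isolation.

## Causal mixture likelihood

The exact marginal likelihood of a z-score under this model is a convolution
over the causal status of every LD partner — infeasible at scale. `pleiomix`
uses a moment-style approximation: for variant j with partner set K_j
(partners at r² ≥ 0.05, self included), the variant's **own** status is
treated exactly (it enters at full weight r² = 1), and its K_j − 1 neighbours
enter through their causal count with the mean neighbour r̄²:

    L_j = Σ_{s,m} Bern(s; π) · Binom(m; K_j−1, π)
          · N(z_j; 0, (s + m·r̄²_j)·n_j·σ_β² + σ₀²).

The split matters: folding the self-partner into the neighbour average makes
the architecture look sparser and stronger than it is (the mixture's heavy
component absorbs the r²=1 self-signal), which biased the recovered shared
count low by roughly a third under realistic LD in development runs; treating
the self-term exactly removes most of that bias while keeping the same
mixture family. The bivariate analogue replaces the Bernoulli with a four-way
category and the binomial with a multinomial over (m₁, m₂, m₁₂); conditional
variances and the covariance add per-component contributions, plus
ρ₀·σ₀A·σ₀B from sample overlap.

Numerical choices:

- **Truncation**: the total causal configuration is capped at m_max = 20 and
  the truncated weights renormalised; binomial tails beyond that are
  negligible at realistic π (levels with weight < 10⁻¹⁶ are also skipped —
  invisible at double precision). Setting m_max = 0 degenerates to the pure
  null model, a useful likelihood check.
- **Partner threshold** r²_min = 0.05: weaker partners contribute noise-level
  variance.
- **Pruning weights**: per-variant weights are inclusion frequencies over 20
  random pruning passes at r² = 0.8, so dense LD regions do not dominate the
  pseudo-likelihood.
- **Optimization**: parameters are transformed (logit π, log variances,
  logit of π₁₂/min(π_A, π_B), atanh correlations) so constraints — including
  π₁₂ ≤ min(π_A, π_B) — hold by construction; a coarse log-spaced grid start
  is refined with Nelder–Mead at tolerance 10⁻⁶ on the transformed step.
  Non-convergence is flagged on the results object, never silent. Fits near
  a boundary (e.g. truth π₁₂ = 0) may exhaust the evaluation budget; the
  returned point estimates remain usable but carry the flag.
- **Speed**: variants sharing a (K, r̄², n_A, n_B) profile share all Gaussian
  mixture constants, which are tabulated once per objective evaluation; the
  kernel then costs one exponential per variant-configuration pair. On very
  heterogeneous real data the profile count is bounded by quantizing r̄² to
  three decimals.
- **Standard errors** are standard deviations over repeated refits on random
  variant subsamples (default 20 iterations at half the variants), warm-
  started from the full-data solution.
- **Two-step bivariate fit**: per-trait polygenicities and variance
  parameters are fixed at their univariate estimates; only (π₁₂, ρ_β, ρ₀)
  are free. Univariate estimation error therefore propagates into the shared
  count — visible as mild shrinkage of π₁₂ in the recovery harness.

Model-fit diagnostics compare the best fit against two degenerate references
— maximal overlap (π₁₂ = min(π_A, π_B)) and independence-expected overlap
(π₁₂ = π_A·π_B) — refitting the correlations under each constraint. The
`reliable` flag requires beating both references by a log-likelihood margin
(default 2.0) *and* both traits clearing a polygenicity floor (default
π ≥ 10⁻³): near-monogenic traits are the model family's known failure mode,
and the flag makes that failure explicit rather than silent.

## Conditional and conjunctional FDR

With the null proportion set conservatively to 1,

    condFDR(p₁|p₂) = p₁ / F̂(p₁|p₂),
    F̂(p₁|p₂) = #{P₁ ≤ p₁, P₂ ≤ p₂} / #{P₂ ≤ p₂},

tabulated on a lattice over (−log₁₀ p₁ ∈ [0,30], −log₁₀ p₂ ∈ [0,10]) at step
0.1, with counts averaged over 20 random pruning passes at r² = 0.1 (one
random representative per LD clique per pass). Per-variant values come from
bilinear interpolation at the variant's own coordinates; −log₁₀ p is clamped
at the lattice bounds. The conjunctional FDR is the per-variant maximum of
the two reciprocal condFDR values; discovery thresholds are condFDR < 0.01
and conjFDR < 0.05, both strict.

- **Inflation control** precedes estimation: λ = mean over pruning passes of
  median(z²) of kept variants, divided by the χ²₁ median (0.45494);
  z → z/√λ with p recomputed. λ < 1 is floored at 1 by default (no
  deflation). All pruned variants are used — no gene-annotation source is
  assumed for an "intergenic" subset.
- **Small strata**: lattice columns whose conditioning stratum holds fewer
  than 100 variants inherit the nearest valid coarser (less stringent)
  column; toys can lower `min_count`.
- **Monotone envelope**: the raw ratio p₁/F̂ is sawtooth in p₁ (it drops at
  each step of the empirical cdf). By default a cumulative maximum along the
  p₁ axis enforces that condFDR is nondecreasing in p₁, a strictly
  conservative envelope; `monotone_p1=False` gives the raw counting
  estimator, which is what exact node-level comparisons against brute-force
  counting use. Because interpolation of node values ≥ their node p₁ chords
  over the convex function 10^(−x), condFDR ≥ p always holds either way.
- **Conditional Q-Q tables** report, per stratum {p₂ ≤ t} (defaults t = 1,
  0.1, 0.01, 0.001), the −log₁₀ nominal p₁ against −log₁₀ of the empirical
  quantile rank/(count+1), averaged over the same pruning scheme. Output is
  plot-ready; nothing is rendered. Empty strata are omitted with a warning.

Under independent-trait null simulations the realized fraction of truly null
variants at conjFDR < 0.05 sits well below the nominal level (the π₀ = 1
convention plus the conservative envelope both bias upward), which the
calibration suite verifies.

## Locus definition

From a discovery set with FDR values: greedy clumping in ascending (FDR, p,
bp, id) order retains variants with r² < 0.6 to everything already retained
(independent significant SNPs); a second pass at r² < 0.1 yields lead SNPs.
Candidates are all variants at FDR < 0.1 with r² ≥ 0.6 to an independent
significant SNP; each independent significant SNP attaches to the retained
lead it is in strongest LD with; per-lead candidate spans are merged on each
chromosome whenever the gap is strictly below 250 kb, iterated to a fixed
point; the merged locus lead is the member lead with the smallest FDR.
Coordinates are 1-based inclusive throughout; BED input is converted on
read. The tie-breaks (p, then bp, then id; leftmost block on equal lead FDR)
are documented choices — the protocol this follows does not specify them —
and make the pipeline byte-deterministic. Variants missing from the LD
reference are treated as independent, with a warning.

Effect direction per locus compares the signs of the lead SNP's z-scores in
the two harmonized GWAS; a zero z-score marks the locus indeterminate and it
is excluded from concordance numerators *and* denominators (with the count
reported). Novelty requires both no physical overlap with any catalog
interval and no candidate SNP in the catalog's known-SNP set.

The extended MHC (chr6:25,119,106–33,854,733) and the 8p23.1 inversion
region are excluded before FDR analysis. No canonical coordinates exist for
8p23.1; the default chr8:7.2–12.5 Mb is the GRCh37 cytoband span and is
configurable.

## Harmonization and replication testing

Two-trait alignment intersects on variant id; trait B's z is negated when its
allele pair is swapped relative to A (directly or via strand complement);
palindromic (A/T, C/G) variants are dropped and counted — allele frequencies
are not assumed available, so frequency-based resolution is out of scope.
Underflowed p = 0 entries are clamped to the smallest positive normal double
before log transforms. Harmonization is idempotent and invariant to allele
recoding of the input, both property-tested.

Replication uses en-masse sign concordance: k of n lead SNPs agreeing in
direction with an independent cohort, p = Σ_{i≥k} C(n,i)·2⁻ⁿ (one-sided
exact binomial, via `scipy.stats.binomtest`). Loci absent from the
replication table are excluded and counted; fewer than 10 discovered loci is
flagged as underpowered. Concordance percentages in the pair-summary tables
are rounded half-up to two decimals.

## Problem sizes in the test and acceptance harnesses

Mixture recovery runs at M = 30,000 and n = 50,000 over ten seeds; FDR
type-I calibration at M = 20,000 over twenty seeds; the end-to-end discovery
+ replication demonstration at M = 10,000 with n = 200,000 (discovery) and
150,000 (replication) so that tens of loci are discovered. Locus-definition
equivalence checks run 100 randomized 30-variant problems against exhaustive
oracles. These sizes were chosen so that every stage is exercised with
clearly interpretable statistics.

## Known limitations

- The count/mean-r² likelihood is an approximation; residual heterogeneity
  among neighbour r² values still shrinks π estimates slightly (a few
  percent at the harness LD; grows with LD strength and range).
- The bivariate fit conditions on univariate point estimates rather than
  propagating their uncertainty; subsampled SEs capture sampling noise of
  the free parameters only.
- The condFDR estimator fixes π₀ = 1 and is therefore conservative by
  design; it estimates an upper bound, not a calibrated FDR.
- Causal-variant counts scale with the reference template size M; for real
  data the reporting template (`M_eff`) is a configuration value, as the
  published counts depend on a reference set whose size must be supplied.
- Strand-ambiguous variants are always dropped; GWAS pairs genotyped on
  different strands lose those sites.
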