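# Methods

This note records the models, the numerical choices and the limits of the
synthetic data, in the package's own words.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Response preparation

The GWAS response is a deregressed EBV per animal and trait.  Deregression
is offered only as the simple shrinkage-inversion rule
`debv = pa + (ebv − pa)/r²` (identity at r² = 1); users holding properly
deregressed proofs skip it.  Records with reliability r² < 0.10 are removed
(the boundary is retained), and the survivors weighted by

w = (1 − h²) / { [c + (1 − r²)/r²] · h² }

with c = 0.40 the fraction of genetic variance not captured by markers.
This is the standard ratio form: it increases with reliability, which is
what a precision weight must do.  Some sources print the same expression
without the division bar; `compute_weight(..., form="literal")` preserves
that product reading (it *decreases* with reliability and is provided only
for comparison).  Weights enter the sampler as residual variance σ²ₑ/wᵢ;
an equivalent alternative (pre-multiplying records by √w) was considered
and rejected to keep the response on its original scale.

## Weighted BayesB

Model and priors:

- y = 1μ + Σⱼ Zⱼ uⱼ δⱼ + e, e ~ N(0, σ²ₑ W⁻¹), W = diag(wᵢ).
- δⱼ ~ Bernoulli(1 − π), π = 0.99 by default: with ~1500–47k markers only a
  few dozen are expected in the model at a time.
- uⱼ | δⱼ=1 ~ N(0, σ²ᵤⱼ); σ²ᵤⱼ ~ scaled-inv-χ²(ν = 4.2, s²), with s² chosen
  so the implied total genetic variance (1 − π) · Σⱼ var(Zⱼ) · νs²/(ν − 2)
  equals the supplied initial genetic variance.  ν = 4.2 is the customary
  weakly-informative choice for locus variances.
- σ²ₑ ~ scaled-inv-χ²(4, s²ₑ) matched to the initial residual variance.

Dosage columns are centered; μ absorbs the mean.  Zero-variance columns are
excluded (model frequency 0); missing dosages are mean-imputed with a
warning.  Each locus update samples (δⱼ, uⱼ) *jointly*: uⱼ is integrated
out of the inclusion odds analytically, so the chain does not suffer the
reducibility of naive Gibbs on (δ, u).  Model frequency is counted over
saved (post-burn-in, thinned) samples; including burn-in would bias it
toward the initial state.  With `pi=0` and `fix_variances=True` the sampler
collapses to a Bayesian ridge whose exact posterior mean
(`weighted_ridge_solution`) serves as an oracle in the tests.  The sweep is
numba-jitted; results are deterministic given the seed (and backend — a
pure-Python fallback exists but draws a different random stream).

Under a null response the posterior inclusion rate is *below* 1 − π: the
marginal likelihood ratio carries an Occam factor √(v/σ²ᵤ) < 1.  It
converges to 1 − π only as the locus variance shrinks; the tests assert
exactly these two properties rather than the naive "null ⇒ prior" reading.

## Windows and Bayes factors

BF = [p̂/(1 − p̂)] / [(1 − π)/π]; p̂ = 1 maps to +inf (serialized "inf" in
TSV).  Evidence classes switch strictly above 3.2 / 20 / 100.  With the
demo chain (500 saved samples) the finest nonzero p̂ is 0.002, so finite BFs
are granular; the full-scale chain (20 000 saved) resolves them finely.

Window shares are computed per saved sample — share_w = var(Z_w u_w)/var(Zu)
across animals — then averaged, because posterior-mean effects underestimate
variance shares (effect signs cancel across samples).  A
`basis="postmean"` variant was considered and dropped: the per-sample rule
is the one whose conservation property (shares sum to 100% when windows are
uncorrelated) is testable.  Windows are half-open 1-Mb intervals,
`floor(bp/1e6)`, labelled `chrom_Mb`; samples with zero genomic variance are
skipped with a warning.  A window is *informative* if its GV% exceeds 1.0
**or** it contains a SNP with BF > 20 (the OR combination, matching how the
two thresholds are used in practice).

## AWM

Selection: (1) BF ≥ 3.2 on the key trait, or on ≥ 2 traits (the key trait
counts toward the two); (2) distance filter; (3) one SNP per gene, ranked by
number of significant traits, then key-trait BF, then lowest coordinate
(a deterministic tie-break; the methodology this follows is silent on ties).
Unannotated survivors are kept as their own rows (toggleable).

**Distance-filter direction.**  `mode="literal"` (default) *eliminates*
SNPs closer than 2500 bp or farther than 1.5 Mb from the nearest gene —
the rule exactly as printed in the methodology this package follows.  The
wider AWM literature keeps SNPs *within* 2500 bp of a gene;
`mode="proximal"` provides that reading.  The two modes partition SNPs
differently (literal excludes genic SNPs, proximal keeps them); both are
idempotent.  Choose deliberately: on dense gene maps "literal" discards
most genic signal.

z-normalization is per trait column, sample SD (n − 1), and is invariant to
affine rescaling of the raw effects, so traits on different scales are
comparable.  Constant columns are an error naming the trait.

## PCIT

Only the algorithm name is inherited; the implementation follows the
original partial-correlation-and-information-theory recipe: for every trio,
first-order partials, local tolerance ε = mean |partial/direct| (ratios with
|direct| < 1e-12 excluded; trio skipped if all three are), and elimination
of an edge dominated through the third node under both inequalities.  An
edge survives iff no trio flags it; surviving edges with |r| ≤ 1e-12 are
dropped as numerical noise.  Trios containing a correlation of ±1 are
skipped (partials undefined).  The kernel is an O(n³) jitted triple loop;
tests verify it against an independently written pair-first brute force on
random matrices up to n = 15.  With only 7 trait columns the row
correlations are high-variance, so edge counts are sensitive to the number
of traits — a property of the design, not a defect.  Trait columns are not
added as network nodes; the network is built on AWM rows only.

## TF validation

PWMs gain a pseudocount of 0.01 (renormalized) before log₂-odds scoring
against a background model (uniform by default).  Scores are discretized to
integer multiples of 1e-3 bits; the null score distribution over background
sequence is computed exactly by dynamic-programming convolution on that
grid, so scan hits (p ≤ 0.001) and reported p-values share one scale, and
enumeration over all 4^L words reproduces the DP exactly.  Scanning is
forward-strand (promoters are oriented upstream flanks) with windows
containing N skipped; a `both-strands` scan was deliberately left out of
scope.  A gene is a target if its promoter has ≥ 1 hit; per-hit calls at
p ≤ 0.001 stand in for the cluster-scoring step of the original workflow,
which is not specified precisely enough to reproduce.  TFs without motifs
are dropped with a warning — mirroring real motif-database coverage — and
the top trio is found by exhaustive search over all 3-subsets with a
lexicographic tie-break.  Note that a motif shorter than 5 bp cannot reach
p ≤ 0.001 against a uniform background (min p = 4⁻ᴸ).

## Synthetic data

The generators emulate the input stack of a medium-density pig study,
scaled so the demo runs in seconds on one CPU (defaults: 3 × 20-Mb
chromosomes, 1500 SNPs, 300 animals, 7 traits with the heritabilities
0.36/0.42/0.35/0.42/0.11/0.10/0.08 typical of production and reproduction
traits, 60 genes, 8 TFs):

- **Map:** uniform positions, markers split evenly across chromosomes.
- **LD:** a Gaussian-copula latent-haplotype model — within each 250-kb
  block every marker's allele indicator loads (ρ = 0.9) on the block's
  latent normal, per gamete; blocks are independent.  This yields tunable
  adjacent-marker correlation (the analysis only needs LD to exist) but not
  the decaying, recombination-shaped LD of a coalescent; `ld_block_bp=0`
  gives independent markers.
- **Traits:** round((1 − π)·m) QTL per trait with N(0,1) effects rescaled so
  var(TBV)/var(phenotype) = h²; DEBV = TBV + noise of variance
  σ²g(1 − r²)/r², with reliabilities r² ~ U(0.1, 0.99] so the reliability
  filter is exercised without emptying the data.  No pedigree is simulated:
  deregression is treated as an upstream input-preparation step.
- **Genes/promoters:** disjoint gene intervals (5–50 kb) placed by gap
  sampling; promoters are i.i.d. uniform ACGT with each TF's consensus
  planted into ~20% of genes at recorded positions.  Sharp PWMs (consensus
  probability 0.85) make planted sites recoverable — which is the point of
  the validation stage test, not a claim about real motif information
  content.

Hence passing tests show the pipeline's machinery is correct under its own
assumptions (sparse effects, block LD, reliability-consistent noise,
independent promoters); they do not show power under realistic LD decay,
polygenic backgrounds, pedigree structure, or compositional promoter bias.

## Problem sizes and determinism

The suite and the acceptance script use demo-scale chains (3000 iterations,
500 burn-in, thin 5) and a 400 × 2000 recovery simulation with 5000
iterations; the classical full-scale settings (110 000 / 10 000 / 5, giving
20 000 saved samples) are the `ChainConfig` documentation default and are
exercised directly in the ridge-limit check (20 000 saved samples).  Every
stage seeds its own generator deterministically from the run seed, floats
are written with fixed formats, and re-running a pipeline config reproduces
its outputs byte-for-byte.

On small simulated genomes the AWM gene set is stochastic, so fewer than
three network genes may be motif-bearing TFs; the pipeline then extends the
candidate set with remaining motif-bearing TFs from the list (logged) so
trio selection always runs.  Real-scale inputs do not need this.
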