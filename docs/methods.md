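# Methods

`corrnull` tests whether the structure of a binary incidence matrix — a
species × sites assemblage or a predator × prey food web — can be explained
by a hypothesized similarity structure among its rows or columns. It does
this by comparing an observed structural metric against three null
ensembles that share identical hard constraints but differ in how swaps are
weighted.

## The link model

For each row *i* of an incidence matrix **A** (n×m), link presence is
modelled as a logistic regression with one structured Gaussian random
effect:

    logit(p_ij) = α_i + b_ij,      b_i ~ Normal(0, σ_i² V)

where **V** is an m×m correlation matrix over the columns (unit diagonal,
positive semi-definite), α_i is the row intercept and σ_i ≥ 0 measures how
much of row *i*'s link pattern the correlation structure explains. The same
model applied to **Aᵀ** with an n×n row-side correlation gives the dual
perspective; for a food web (rows = consumers) the two perspectives are the
*predator's diet* (V over resources) and the *prey's consumers* (V over
consumers).

### Estimation

There is one binary observation per random-effect level, so the marginal
likelihood is an m-dimensional integral. We maximize its Laplace
approximation over (α, log σ): an inner Newton iteration (with step
halving) finds the posterior mode b̂ of the effects, and L-BFGS-B drives
the outer surface, warm-starting the mode between evaluations. Numerical
safeguards, in order of application:

* **Degenerate rows** (all 0 or all 1) carry no information about σ; they
  return the Laplace-smoothed uniform probability (s+1)/(m+2) with σ = 0,
  so every cell always has a defined weight.
* **Singular correlation structures** (constant, zero-nugget groups) are
  repaired before inversion: eigenvalues clipped at 0, jitter 1e−8 added,
  diagonal rescaled to 1. Matrices with an eigenvalue below −1e−6 are
  treated as genuinely indefinite and rejected rather than repaired.
* **Perfect separation** is damped by a weak Gaussian penalty on α
  (sd 10); the same penalty is included in the test oracle so both target
  the same estimand.
* **σ probes**: before running the optimizer, the Laplace likelihood is
  probed at σ ∈ {0.25, 0.75, 2} with the intercept-only α. If no probe
  beats the σ = 0 likelihood by 0.05, the intercept-only fit is returned
  directly. The probes also select the optimizer's starting point.
* The σ = 0 limit is always evaluated exactly and kept if it scores at
  least as well as the Laplace optimum; σ is searched in [1e−4, 20] on the
  log scale with a boundary warning.
* Fitted probabilities are clipped to [1e−6, 1−1e−6] so that the informed
  swap acceptance probabilities below stay strictly positive (the chain
  remains ergodic).

Validation: for m ≤ 3 the fit agrees to within 1e−2 in p with a grid-search
maximizer of the numerically integrated (tensor Gauss–Hermite) marginal
likelihood, for independent and exponentially correlated effects. Two known
limitations. First, for m = 2 with one link and one non-link the exact
profile likelihood is *constant* in σ at the optimal α, so p is determined
only up to the tie-breaking of a flat ridge; such cases are excluded from
the oracle comparison. Second, designs in which V has very few effective
levels cannot identify σ: with two equal groups the intercept absorbs the
mean of the two group effects and σ̂ is built from a single contrast
(median σ̂ ≈ 0.67·σ/√2·2 ≈ 0.72 for σ = 1.5 regardless of m). Recovery
simulations therefore use 20 equal groups at m = 400, where the median over
50 simulations recovers α within ±0.3 and σ within ±0.4.

## Correlation structures

* `constant_correlation` — all ones; provably uninformative (within-row
  probabilities become constant, and the informed model reduces to the
  uninformed one).
* `group_correlation` — 1−η within a group, 0 between.
* `exponential_correlation` — off-diagonal (1−η)·exp(−d_ij/D_max), with
  d_ij the Euclidean trait/coordinate distance and D_max the largest
  pairwise distance. Normalizing by D_max makes the decay scale adapt to
  the trait cloud; the printed source formula is typographically ambiguous
  between d/D_max and D_max·d in the exponent, and we adopt the standard
  decay form, recording it in the matrix provenance.
* `phylogenetic_correlation` — shared root-to-MRCA branch length,
  standardized to a correlation. Standardization loses only scale, which
  σ_i recovers.

The nugget η defaults to 0.01 everywhere one is accepted. The *misinformed*
control applies one uniformly random permutation to both axes of V, which
preserves its eigenvalues and off-diagonal value multiset while destroying
the pairing of elements to correlations.

## Randomization

All models are fixed–fixed swap chains: repeatedly draw two distinct
existing links i←j and l←m uniformly, propose i←m and l←j, and apply the
proposal only if it violates no constraint. Invalid or rejected proposals
are self-transitions. For bipartite matrices the constraints are empty
target cells and i≠l, j≠m (row and column sums are conserved exactly). For
food webs, swaps additionally respect the link classes: single links swap
only with single links and may not create a self-loop or the reciprocal of
an existing link; double (reciprocal) links swap as atomic unordered pairs
against other double links, with each pair's orientation drawn uniformly
per trial so both rewirings are reachable; self-loops (cannibalism) never
move. In/out degrees and single/double/cannibal counts are conserved
exactly and asserted for every replicate.

Acceptance rules: the uninformed model accepts every valid proposal. The
informed model accepts with probability p_im·p_lj — the product of the
estimated probabilities of the links being *created* (for a double-pair
swap, the product of all four created directed links, assuming
independence). The probabilities are estimated once, before randomization
begins, so every swap is informed relative to the original matrix. Because
the acceptance ratio between forward and reverse moves telescopes into the
product of link probabilities, the chain's stationary distribution weights
each fixed-marginal matrix by the product of its links' probabilities; the
uninformed chain (symmetric proposals, acceptance 1) is uniform over the
fixed-marginal class, which we verify against a brute-force enumeration.
An optional Metropolis-style variant that also divides by the destroyed
links' probabilities would target the same family; we implement the
create-only rule as the primary definition and do not expose alternatives.

Stopping rule: the chain stops after 2×(number of 1s) *accepted* swaps,
with a trial cap of 100× as a safety net (a warning reports capped runs).
Counting accepted swaps rather than trials is stricter than treating the
recommendation as an expectation. Informed chains with skewed probabilities
accept only a small fraction of proposals, so the benchmark workflows raise
the cap to 2000× the link count; otherwise informed and misinformed
ensembles stop far short of the accepted-swap target and model comparisons
conflate mixing length with the null hypothesis.

The misinformed model redraws a fresh permutation of V and re-estimates the
probabilities for every replicate. Per-replicate seeds are derived
deterministically from the master seed; identical inputs and master seed
reproduce an ensemble exactly.

## Metrics and testing

* **Motif census** — all C(n,3) induced three-node subdigraphs, self-loops
  dropped, classified into the 13 connected triad classes (standard triad
  taxonomy). The five named food-web motifs map, under the rows-eat-columns
  convention, to: exploitative competition 021D, apparent competition 021U,
  food chain 021C, omnivory 030T, three-species loop 030C. The census is
  verified against an exhaustive-permutation isomorphism oracle.
* **NODF** — decreasing-fill convention: an (unordered) pair of rows
  contributes 100·(shared 1-columns)/(poorer row's fill) when the
  marginals strictly decrease and 0 when they tie or the poorer row is
  empty; likewise over column pairs; NODF is the mean over all
  n(n−1)/2 + m(m−1)/2 pairs. This equals the published calculator applied
  to the matrix sorted by decreasing marginals (cross-checked against R
  vegan `nestednodf(order=TRUE)`), and is therefore invariant under row and
  column permutations. Perfect nesting with all-distinct marginals gives
  exactly 100; a checkerboard gives 0.
* **z-scores** — z = (k − ⟨k*⟩)/σ{k*} with the sample (n−1) standard
  deviation; |z| ≥ 1.96 (the two-decimal upper 2.5% normal quantile) marks
  significance. A zero-spread ensemble yields an undefined z with a
  warning. Ensembles of ≥ 200 replicates are recommended; the benchmark
  uses 60 for runtime and inherits correspondingly larger Monte-Carlo
  error.
* **Overlap fraction** — the share of observed links present in a
  replicate; reported per ensemble to separate genuine null-hypothesis
  differences from differences in how far chains move.

## Synthetic data

`synthetic_foodweb` draws the random-effect matrix B matrix-normally with
the species phylogeny on both sides, B = β·L Z Lᵀ (L Lᵀ = V): each
consumer's effect vector is marginally Normal(0, β²V) — exactly the link
model's generative direction — and related consumers additionally share
correlated diets. The consumer-side coupling matters: if rows are drawn
independently, every cross-consumer statistic matches the
degree-conditioned null in expectation, so the webs carry *no* motif signal
a fixed–fixed null could detect (we verified that uninformed mean |z|
then sits at E|N(0,1)| ≈ 0.8). Row intercepts are solved so each row's
expected density hits the target; the diagonal is kept empty. β = 0 gives
an Erdős–Rényi-style control. For benchmark worlds we use a balanced clade
tree (5 clades × 6 tips, within-clade correlation 0.85, `clade_tree`)
because pure-birth correlations are too diffuse for 30-observation rows to
recover; pure-birth trees remain the default for generic fixtures.

`synthetic_assemblage` generates sites × species matrices with a geometric
site-richness gradient (ratio γ, richest site holding 70% of the pool by
default) and species drawn per site without replacement with weights
exp(−λ·rank/n): λ large gives nested structure, λ = 0 a random control at
the same richness gradient. Site coordinates and areas are emitted for
building exponential correlation structures.

What these generators do *not* emulate: body-size or niche-based link
topology (no cascade/niche model), sampling error, quantitative link
strengths, or the empirical phylogenies of any real system. Passing the
benchmark shows the machinery is self-consistent — structure generated
from the model's own direction is detected and explained away by the
matched informed null — not that any particular real community is
phylogenetically structured.

## Benchmark design and problem sizes

The structured-data benchmark uses 4 worlds of 30 species at density 0.18
with β = 2, ensembles of 60 replicates per model, and compares the mean
|z| over motif classes whose null is non-degenerate under all three
models. Expected pattern: informed < uninformed ≈ misinformed at β = 2
(computed by the test suite: means 0.77 vs 1.11 vs 0.99 over the four
worlds), all three equal within Monte-Carlo error at β = 0 (0.94 vs 0.88
vs 0.90). "Within Monte-Carlo error" is operationalized as three
standard errors of the paired across-world differences (floored at 0.2,
the scale of residual ensemble noise). The uniformity check records every
20th state of a 10⁵-step chain because raw successive states are
autocorrelated and would invalidate the χ² calibration.
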