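# Methods

## Data model

A gene tree is rooted, strictly binary and time-calibrated (branch lengths
in million years, My). Every internal node carries exactly one event tag —
`SPECIATION`, `DUPLICATION` or `NA` — read from NHX comments
(`[&&NHX:Ev=spec|dup|na]`, or `D=Y/N`); unannotated internal nodes default
to `NA` with a logged count, and multifurcations are rejected at ingest
because both the contrasts and the Gaussian likelihoods assume binary
trees. Trees are expected ultrametric within a relative tolerance of 1e-6
of tree height; operations that deliberately break the time calibration
(bias injection, branch-length transformation) flag the result as
non-ultrametric, and node age is then defined as the mean distance to the
node's descendant tips. Node *age* is measured to the tips, *height* from
the root, *depth* in nodes with the root at 0 — three distinct diagnostic
predictors.

Tree-level filters mirror standard practice for this kind of analysis:
trees with negative branch lengths are excluded (not clamped); trees need
at least 4 tips with trait data, at least one speciation and at least one
duplication node; tips without trait data are pruned with unary nodes
collapsed (branch lengths summed, so patristic distances among retained
tips are preserved exactly; event tags of collapsed nodes are dropped and
counted). Nested speciation nodes sharing a clade label — which would
force zero-length branches during calibration — are repaired by re-tagging
all but the oldest as `NA`; same-label nodes on disjoint paths are left
alone, since the zero-length argument only applies along a single
root-to-tip path.

## Contrasts, signal, diagnostics, transformation

Contrasts follow the standard pruning recursion; only |contrast| is used
downstream because the sign depends on arbitrary child ordering. A
zero expected variance (two zero-length child branches) is an error by
design: silently padding with an ε would alter the very quantity whose
bias is under study.

Blomberg's K is computed as (MSE₀/MSE)obs divided by its Brownian
expectation [tr(C) − n/(1ᵀC⁻¹1)]/(n−1), where C is the matrix of shared
root-to-MRCA path lengths, MSE₀ uses raw deviations from the phylogenetic
mean â = (1ᵀC⁻¹x)/(1ᵀC⁻¹1) and MSE the C-whitened ones. The permutation
p-value is the add-one-corrected share of tip relabelings with MSE at most
the observed (small MSE = strong signal). The strong-signal cutoff
defaults to K > 0.551. Mean K over 500 BM simulations on a fixed 32-tip
tree is ≈ 0.99 in this implementation.

The diagnostic battery correlates |contrast| with expected SD, log₁₀ node
age, node height and node depth; all four must have p ≥ α (default 0.05,
boundary passing) for a tree's contrasts to be used. Pearson correlation
is the default (matching the classical contrast-standardization
literature); Spearman is available. Zero-variance predictors or responses
pass vacuously with a "degenerate" note; nodes with age ≤ 0 are dropped
from the age test only. The log base is cosmetic for the Pearson p-value
and is fixed at 10. On BM data the pass rate is ≈ 0.86 — slightly above
the (1−α)⁴ ≈ 0.815 that four *independent* tests would give, because the
four predictors are correlated on small trees.

The transformation search evaluates all 21 powers b ↦ bᵉ,
e ∈ {0, 0.1, …, 2}, plus log₁₀ b. log₁₀ is admissible only when every
branch exceeds 1 My, since shorter branches would map to non-positive
lengths and PIC requires positive variances. Among candidates whose
|contrast|-vs-SD correlation has p ≥ α the one with smallest |r| is chosen
(ties toward the exponent closest to 1, then the smaller) — a
deterministic, order-independent rule in place of the ambiguous
"first non-significant" scan. The chosen tree is re-checked with the full
four-test battery; if no candidate passes, the tree is flagged excluded.
After transformation the young/old distinction is not applied downstream:
transformed branch lengths carry no absolute age.

## Trait-evolution models

Branches are painted with the event class of their parent node, with
duplications split young/old at the maximum speciation age of the tree
set (AUTO) or a supplied threshold (boundary inclusive for young). The
`NA` regime is retained as its own regime in BMM/OUM but never enters
speciation-vs-duplication comparisons; regimes absent from a tree are
dropped from its parameter vector.

All four models are Gaussian. BM covariance accumulates σ²ₖ × branch time
along shared root paths (per-regime shared-time matrices are precomputed
once per tree). The OU mean weights each regime's optimum θₖ by
Wᵢₖ = ∫ α e^{−α(Tᵢ−t)} dt over the times tip i's root path spends in
regime k, with the residual weight e^{−αTᵢ} assigned to the root-adjacent
regime's optimum (fixed root pinned there — the default, adding no free
parameter; a stationary-root option replaces the covariance by
σ²/(2α) e^{−α dᵢⱼ} and is centred on the same optimum). The fixed-root
covariance is σ²/(2α) e^{−α dᵢⱼ}(1 − e^{−2α tᵢⱼ}) with d the patristic
distance and t the root-to-MRCA time.

Fitting: the BM mean and the OU optima are profiled out by GLS (via a
least-squares solve that tolerates the near-collinear OU design at very
small α), and the overall rate scale is profiled analytically, so BM1 is
closed form, BMM optimizes only m−1 log relative rates (L-BFGS-B,
5 restarts from N(0, 1.5) perturbations with a per-tree seed), and OU1/OUM
reduce to a bounded 1-D search over log α ∈ [log 1e-8, log(100/T)]
(40-point grid plus Brent refinement). Parameter counts are BM1 = 2,
BMM = m+1, OU1 = 3, OUM = m+2; models with n − k − 1 ≤ 0 are skipped for
that tree. A fit counts as converged only if the optimizer succeeded, α is
interior to its bounds, and the central-difference Hessian of the negative
log-likelihood at the optimum (in log-rate/log-α coordinates) is positive
definite; non-convergent fits are excluded from selection. This makes the
OU fit on genuinely Brownian data (α driven to its lower bound, flat
likelihood) drop out gracefully rather than spuriously win. Selection uses
AICc = −2lnL + 2k + 2k(k+1)/(n−k−1) and Akaike weights; exact ties go to
the model with fewer parameters, then the fixed order BM1, BMM, OU1, OUM.
Invariant traits short-circuit to a "trait-invariant" report.

Verification is dual-route throughout: contrasts against a successive-GLS
orthogonalization oracle (and against ape::pic through Rscript on a
fixture), BM likelihoods against dense covariance matrices assembled by
brute-force path enumeration, OU likelihoods against quadrature means and
an ODE-integrated variance recursion, all to 1e-8 or better, plus the
OU → BM limit at α = 1e-8.

## Hypothesis layer

Pooled contrasts are compared with the rank-sum test on |contrast|
(exact null when both groups have ≤ 50 tie-free observations, otherwise
the tie-corrected normal approximation); duplication contrasts are
stratified young/old where ages are meaningful, with the speciation pool
shared between strata. Per-tree quantities (σ² on BMM-best trees, θ on
OUM-best trees) use the paired signed-rank test, two-sided, restricted to
trees containing both compared regimes. No multiple-testing correction is
applied across strata. Randomization studies permute either tip traits
(phylogenetic structure destroyed, node events kept) or node events
(multiset preserved, age classes re-derived); under the model-fitting
analysis the best model per tree is frozen from the unrandomized run and
only its parameters are re-estimated.

## Synthetic data: what it emulates, and what it does not

The default species tree is an eight-tip ladder with speciation ages
(296, 167, 160, 90, 29, 9, 6) My — the root age being the oldest
calibration point of the eight-vertebrate setting; interior ages are
plumbing defaults. Within the species tree, duplications arrive at
λ = 0.002 per lineage per My and each new duplicate subtree is lost with
probability 0.3. Ancient duplications (the unconstrained ones) arrive at
0.002 per My over (296, 1175] My — the upper limit matching the oldest
plausibly calibrated duplication age in the motivating data — and are
chained above the root; the rate was chosen to bring the old:young
duplication composition toward the empirical tree sets (realized ratio
≈ 0.34, ≈ 6 young and ≈ 2 old duplications per tree). Realized tree sizes
have median ≈ 28 tips (mean ≈ 37): with whole-subtree loss, matching the
empirical old/young mix makes trees somewhat larger than the empirical
median of ~15 tips; a per-lineage birth–death loss process would decouple
the two but is a different model than the one specified here.

Bias injection draws one log-uniform [1, 100] factor per branch whose
parent is an old duplication and multiplies that branch length,
reproducing "unconstrained calibration" above the oldest speciation:
the expected SDs of contrasts at old-duplication nodes inflate, everything
below the threshold is untouched, and the tree becomes non-ultrametric.
Traits are always simulated on the *true* (unbiased) tree; the biased copy
is what the analyst sees — the same asymmetry as real miscalibration.

Traits are unbounded even though empirical τ lives in [0, 1]: PIC, BM and
OU all assume unbounded support and the validation logic relies on it.
Consequently the simulations do not emulate boundary compression of τ near
0/1, rate heterogeneity across genes beyond the event classes, measurement
error in τ, or gene-tree topology error — passing tests show the methods
behave correctly under their own assumptions plus the calibration
artifact, not that any particular empirical data set satisfies them.

OC (ortholog-conjecture) simulation multiplies σ² by ρ on branches whose
parent is a duplication — exactly the regime-painting rule, keeping
simulation and inference aligned. ρ defaults to 4 in the validation
studies (contrast magnitudes scale as √ρ = 2).

## Calibration facts established by the test suite

Problem sizes were chosen to give stable Monte-Carlo estimates at
interactive runtimes (the full suite runs in ≈ 2 minutes): 500 null
studies of 50 trees for type-I calibration (two-sided rejection ≈ 4–5%,
inside the 99% binomial band); 50 biased null studies for the
pseudosignal (reverse trend with p < 0.05 in ≥ 90%, persisting under tip
permutation) and its rescue; 50 OC studies of 300 trees for power
(one-sided detection in ≥ 80% for both gated approaches — in practice
p-values are astronomically small at these sizes); 200 trees of 64 tips
for BMM/OUM recovery (median σ̂²-ratio ≈ 3.8–4.0 for a true ratio of 4;
θ ordering recovered in ≈ 100%; AICc picks the generating model in a
clear majority).

One honest imperfection: the transformation-rescue pipeline is slightly
anticonservative — its true two-sided rejection rate on biased null
studies is ≈ 8% against a nominal 5% (measured over 300 studies). Pooling
contrasts across trees that each received their own power transformation
mixes heterogeneous scales, and the per-tree gating cannot fully remove
the between-tree component of the bias. At the 50-study scale used for
acceptance this stays within the 99% binomial band around nominal.

## Known limitations

- Time calibration itself (penalized likelihood) is out of scope; the
  calibration artifact is emulated by the bias switch, not by re-running a
  calibrator.
- Bayesian reversible-jump detection of optimum shifts is not implemented;
  regime placement is deterministic from the known node events.
- The rank-sum comparison treats pooled contrasts as exchangeable across
  trees; with per-tree transformations this is only approximately true
  (see above).
- OU fits on trees with few tips per regime are weakly identified in α;
  the Hessian gate removes most such fits but the OUM optima for rarely
  visited regimes remain noisy.
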