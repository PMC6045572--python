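# Methods

## The attractor network

The semantic layer is a single, fully recurrently connected layer of
logistic-sigmoid nodes, one per semantic feature, driven by a static
visual input vector.  The dynamics per tick are leaky integration of a
weighted input sum followed by a sigmoid (see README for the equations).
The integration constant `c` controls how much the current external
input dominates over the accumulated input; `c = 1` removes temporal
integration entirely.  Connection weights (input, recurrent, bias) are
initialised Uniform(0, 0.05) and the tick-1 activation template
Uniform(0, 0.10); the tick-1 state carries no item information and is
excluded from every stage analysis.  Self-connections in the recurrent
layer are clamped to zero by default to prevent trivial
self-amplification.

Training is continuous recurrent backpropagation through time.  The
loss is the cross-entropy between activations and the binary feature
targets, accumulated at every tick from `t_err = 2` to `T` (error
injected throughout the settling process, not only at the end), summed
over features and ticks and averaged over items.  Value-0 targets
contribute fully, so spurious activation of non-target features is
penalised.  Optimisation is plain batch gradient descent with momentum
0.9 and learning rate 0.01.  A run is declared converged at the first
epoch where ≥ 95% of target (value-1) features reach activation ≥ 0.70
at the final tick; non-convergence within the epoch budget raises a
warning, never a silent pass.  The analytic BPTT gradients are verified
against central finite differences (relative error < 1e−4) in the test
suite.

Defaults: `c = 0.25`, `T = 20` ticks, 20 input units, at most 2,000
epochs.  `c` is not pinned down by theory; the qualitative behaviour of
the package holds across `c ∈ {0.1, 0.25, 0.5}` (training converges and
the feature-dynamics orderings persist).  Numerical safety: the sigmoid
uses the stable piecewise form and cross-entropy activations are clipped
to [1e−7, 1 − 1e−7].

## Synthetic study conditions

The generators produce every input of the pipeline with known ground
truth; their defaults are the package's study conditions and are fixed.

**Feature norms** (60 concepts, 6 categories, 14 features per concept,
~290 features).  Each concept's budget splits into three sharedness
tiers: category features shared by one category's members (high but
imperfect coherence, 0.9), superordinate-like cross-category features
that cover two or three whole categories and come in correlated pools of
three near-identical columns (emulating the dense inter-feature
correlations of highly shared properties — *is green* spans plants and
vegetables), and distinguishing features with N ≤ 2 (singletons plus
occasional within-category pairs).  Feature types are sampled from a
visual-heavy mixture, tilted so visual types are over-represented among
shared features and under-represented among distinguishing ones, as in
property-norm corpora.  The coherence and pooling choices matter: they
give highly shared features both strong visual support and strong
mutual correlation, which is what makes them activate fastest once the
network is trained.  Real norms differ in ways the generator does not
emulate — graded production frequencies, polysemy, far larger and
unbalanced categories — so passing tests demonstrate the mechanism, not
corpus-level statistics.

**Visual embeddings** are a standardised random linear image of each
concept's visual-type feature vector, weighted by `visual_coupling`
(default 0.8), plus Gaussian noise (`noise_sd = 0.5`).  Concepts sharing
visual features therefore have correlated embeddings — the regularity
the attractor network learns to exploit.  The embedding matrix is
SVD-reduced to the network's input dimensionality (`svd_reduce` returns
rank-k scores and the retained variance fraction).  Note that a rank-k
SVD projection preserves Euclidean geometry losslessly at full rank but
not the Pearson-correlation RDM exactly, because rotating coordinates
changes per-pattern means; correlation RDMs of reduced and original data
agree approximately, increasingly so with k.

**Visual stage trajectory**: layer 1 is an item-specific random
"pixel-like" matrix, layer L the embeddings, intermediate layers convex
blends with weight `((l−1)/(L−1))^0.7`.  The concave exponent keeps
layer 2's embedding share well above the sampling jitter of rank
correlations on ~1,800 RDM pairs, so RDM agreement with the embedding
geometry increases monotonically in depth.

**Synthetic brain**: regions are consecutive multi-plane boxes along the
first grid axis (the synthetic posterior-to-anterior axis) on an 8×8
plane, each spanning ≥ 2 planes, separated by 3 background planes so a
radius-2 searchlight sphere can never straddle two regions.  For each
subject and region the generative stage's centered item patterns are
passed through a subject-specific random mixing matrix with orthonormal
rows orthogonal to the constant vector — a construction that preserves
pairwise Pearson correlations exactly, so the noiseless region RDM
equals the generative stage RDM — scaled to unit signal variance, plus
i.i.d. Gaussian noise of standard deviation 1/snr (default snr 2,
12 subjects).  Background voxels are unit-variance noise.  The voxel
grid is abstract (no mm units): the gradient claim concerns stage order,
not anatomy.

Default planted regions: EVC ← visual layer 1, pVTC ← semantic tick 3
(an early tick, where shared/visual features dominate), PrC ← semantic
tick 20 (the fully settled meaning).

## RSA layer

First-order dissimilarity is 1 − Pearson over patterns; second-order
comparison is Spearman's rho over the strict lower triangle.  The ROI
permutation test relabels items (joint row+column permutation of the
neural RDM, model RDMs fixed) and uses the add-one rule
p = (1 + #{null ≥ observed}) / (1 + n_perm), Bonferroni-corrected across
model stages.  The noise ceiling's lower bound is the leave-one-subject-
out mean Spearman agreement with the averaged remaining subjects.

The searchlight sweeps a Euclidean sphere (radius in voxel units,
default 2 — roughly a 7 mm sphere at 3 mm voxels) and scores all stage
RDMs per sphere in one pass.  Group inference Fisher-z-transforms the
per-subject maps, optionally smooths them on the grid, and tests mean
> 0 by sign-flip permutation (exhaustive enumeration with a warning when
2^subjects ≤ n_perm), followed by Benjamini–Hochberg FDR.  This is a
deliberate, smaller-surface substitute for variance-smoothed pseudo-t
cluster software: the error-control intent (voxel-level FDR on a
one-sample permutation test) is the same, and the pseudo-t map is
reported alongside.  The composite map assigns each voxel significant
for ≥ 1 stage the argmax-rho stage, ties resolved toward the earlier
stage (conservative with respect to claiming semantic fits).

A caveat discovered during development and reflected in the tests: late
attractor ticks converge toward a fixed point, so their RDMs become
*rank-identical* (adjacent-stage Spearman reaches 1.0).  The best-fit
stage within that late band is therefore unidentifiable in principle;
recovery of a late planted stage is assessed as (i) strict recovery of
the posterior-to-anterior ordering, (ii) ±1-stage recovery for the
visual and early-semantic regions, and (iii) representational
equivalence (rho ≥ 0.99 between recovered and planted stage RDMs) for
the late region.

## Stage-gradient analysis

A full mixed-effects fit is replaced by a two-stage summary-statistics
scheme: pooled OLS with subject fixed intercepts for model comparison,
per-subject coefficients averaged for the reported curve, permutation
for inference.  Restricted cubic splines use the Harrell basis with
knots at the standard quantiles (3 knots: 0.10/0.50/0.90; 4:
0.05/0.35/0.65/0.95; 5: 0.05/0.275/0.50/0.725/0.95); the basis is
linear beyond the boundary knots and twice continuously differentiable
at the knots (both verified by finite differences).  Knot count grows
from linear through 3/4/5 knots while a partial F test on the pooled
fit improves at α = 0.05 — a likelihood-ratio-style criterion; the
candidate bases are not strictly nested across knot counts, so the test
is approximate and is used only for selection, not inference.

Shape classification: a fitted curve is *peaked* only when its interior
maximum exceeds the values at both endpoints by more than 2% of the
fitted range; otherwise the endpoint comparison decides increasing vs
decreasing (numerically constant curves are flat).  The tolerance exists
because spline fits of steep saturating profiles wiggle by ~1% of range
on plateaus; requiring a material interior peak keeps the classification
stable without hiding genuine peaks (the early-semantic region's real
dip is ~3% of range).

The region × stage interaction statistic is the partial F comparing
region-specific spline curves against a shared curve (subject
intercepts in both models); its null permutes each subject's region
labels independently, preserving stage structure.  With two regions the
permutation group contains the identity and the global swap, both of
which reproduce the observed F exactly; this atom (2/2^subjects) bounds
the attainable p-value from below, which is why power checks use 12
subjects.  Calibration and power of the test are verified by Monte
Carlo in the acceptance suite.

## Problem sizes and runtimes

The default conditions (60 concepts × ~290 features, 20 ticks, 12
subjects, ~1,700-voxel grid, 26 stages) were chosen so that a full
pipeline run takes ~15 s on one CPU and the entire test suite, including
five end-to-end runs and the Monte-Carlo calibrations (1,000 null ROI
datasets, 500 interaction nulls, 500 pure-noise FDR datasets), finishes
in a few minutes.  All randomness flows from one top-level seed through
named substreams (norms, embeddings, visual trajectory, network, brain,
permutations), keyed by a stable CRC of the substream name so runs are
bit-reproducible across processes.

## Known limitations

- The synthetic norms are far smaller than real property-norm corpora;
  absolute training-epoch counts and weight magnitudes are not
  comparable to runs on real norms.
- The noise model (i.i.d. Gaussian per voxel, subject-specific linear
  mixing) is the simplest under which RSA recovery is well-posed; real
  fMRI noise is spatially and temporally correlated.
- The pipeline recomputes all stages on each call rather than caching
  intermediate artifacts to disk; at the default scale a run is seconds,
  so cache invalidation complexity is not warranted.
- Exact mixed-model F statistics (REML, Satterthwaite degrees of
  freedom) are out of scope; the permutation analogue answers the same
  scientific question.
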