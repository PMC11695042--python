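# Methods

`blockpls` implements a block-structured latent-variable workflow for
mapping a quantitative phenotype onto a high-dimensional genotype matrix
in the small-n/large-p regime: gene blocks are discovered by clustering
variables, a modified multiblock PLS is fitted across the blocks,
block-level importance statistics (BIP and its weighted variant BwIP)
retain the influential blocks, and VIP retains the influential genes
within them. A group lasso over the same partition serves as the
penalized-regression baseline, and a synthetic generator provides ground
truth for power and benchmarking studies.

## Model and fitting

Let X be the n × p autoscaled predictor matrix partitioned column-wise
into C blocks X = [X(1) | … | X(C)] with sizes l(c), and y the centred
response. For components r = 1…R the fit computes

- within-block weights u_r(c) = E(c)'f / ‖E(c)'f‖ (unit norm),
- within-block scores s_r(c) = E(c) u_r(c),
- the super-score design S_r = [s_r(1)/l(1) | … | s_r(C)/l(C)],
- super-weights w_r = S_r'f / ‖S_r'f‖ (unit norm),
- super-score t_r = S_r w_r, loadings p_r = E't_r/(t_r't_r) and
  q_r = f't_r/(t_r't_r),
- deflation E ← E − t_r p_r', f ← f − t_r q_r,

starting from E = X, f = y. The division of each block score by its
block size is the deliberate modification relative to classical
multiblock PLS: without it a large diffuse block dominates the
super-score purely through its dimension. The same normalization is used
when predicting, which is required for the basic contract
predict(training data) = fitted values; dropping it at prediction time
breaks that identity. With C = 1 the factor cancels through p_r and q_r
and the model is algebraically identical to orthogonal-scores NIPALS
PLS1 (verified against an independent implementation to 1e-8).

Degenerate directions are handled by early stopping: if every block's
weight norm, the super-weight norm, or t't falls below the tolerance
(default 1e-12 on squared norms) extraction stops and the effective
component count is recorded; an individual degenerate block contributes
a zero weight vector at that component rather than aborting the fit. A
model with zero effective components predicts the training-response
mean.

Implied regression coefficients use the standard PLS closed form
b = A(P'A)⁻¹q with A the per-component composite weights
(w_r(c)·u_r(c)/l(c) per block segment); this reproduces the iterative
predictions to numerical precision and enables direct comparison with
the generator's true coefficients.

## Importance statistics and selection rules

With cov_r = cov(y, t_r) (1/(n−1) denominator, taken against the
original centred response; a switch selects the running residual
instead — both conventions appear in the literature and the ratio form
of BIP makes the choice invisible there, but BwIP's mixed numerator
makes it visible, so it is fixed and documented):

    BIP(c)  = C Σ_r cov_r² w_r(c)²            / Σ_r cov_r²
    BwIP(c) = C Σ_r cov_r² U_r(c) w_r(c)²     / Σ_r cov_r²,
              U_r(c) = ‖u_r(c)‖² / p_c

Since ‖w_r‖ = 1, mean over blocks of BIP is exactly 1 — the property
that makes the "BIP > 1" cutoff meaningful. U_r(c) is the mean-square
within-block weight; with unit-norm u it equals 1/p_c, so for equal-size
blocks BwIP = BIP/p_c. BwIP therefore deliberately penalizes large
diffuse blocks and concentrates selection on small coherent ones; a
consequence is that for blocks larger than C variables BwIP cannot
exceed 1, and block retention under the BwIP rule then falls through to
the fallback (below). A literal variant that removes the covariance
weighting from the numerator is available behind a flag; the weighted
reading is the default because it keeps the numerator and denominator in
the same units and reduces cleanly to BIP/p_c.

VIP uses per-variable composite weights v_jr = w_r(c(j)) u_jr / l(c(j)),
renormalized to unit norm per component, weighted by the explained
response sum of squares SS_r = q_r² t_r't_r:

    VIP_j = sqrt( p Σ_r SS_r v_jr² / Σ_r SS_r ),

so Σ_j VIP_j² = p and VIP > 1 flags above-average variables. With one
block this is exactly the standard chemometrics VIP. An alternative
(refitting a single-block PLS per retained block and applying
single-block VIP) was considered; the joint-fit definition is the
default because it uses the same latent space that selected the blocks.
The absolute loading weight of a variable is mean_r |v_jr|, thresholded
at 0.2 by convention; VIP systematically selects fewer variables than
the loading rule at these cutoffs.

Selection cutoffs (block statistics > 1, VIP > 1, |loading| > 0.2) are
configuration values defaulting to the conventional choices. If no block
(or no variable within a retained block) clears its cutoff, the single
top-ranked block (or top variable per block) is kept, so weak-signal
data degrades to a minimal model rather than a dead end; the combined
"both" block rule ranks its fallback by min(BIP, BwIP).

## Pipelines and error estimation

The pipeline order is: (1) choose R by K-fold CV on all blocks; (2) fit;
(3) compute importance; (4) retain blocks by the method's statistic;
(5) re-choose R and refit on the retained blocks; (6) retain variables
by VIP within those blocks; (7) re-choose R and refit on the selected
variables. R is re-selected after each filter because the effective
dimensionality changes materially; filtering is one-pass by default with
an iterative mode that repeats block elimination to a fixed point. The
`pls` method is the C = 1 special case and `mbpls` skips steps 3–7.

Folds are stratified by response quantile (consecutive rank chunks with
within-chunk shuffling), which stabilizes fold composition at the small
sample sizes this method targets (tens of genomes). Scaling parameters
are refit inside each training fold and applied to the held-out fold, so
preprocessing never sees held-out data. The calibrated RMSE is computed
on the full training data; the validated RMSE wraps the entire pipeline
— including both selection stages — inside a fresh CV loop, the
statistically safe convention that keeps selection optimism out of the
estimate.

## Group lasso

The baseline solves ½‖y − Xβ‖² + λ Σ_g ω_g‖β_g‖ on autoscaled data with
ω_g = p_g by default (the √p_g convention is available behind
`group_weights="sqrt"`). The solver is cyclic block coordinate descent
with blockwise proximal steps at the block Lipschitz constant
L_g = ‖X_g‖²: exact one-step group soft-thresholding for orthonormal
blocks, a monotone majorize-minimize update otherwise (objective never
increases; KKT residuals reach 1e-8 on random problems). λ_max, the
smallest penalty killing every group, is computed from the
soft-threshold condition ‖X_g'y‖ ≤ λω_g and anchors a 3-decade
logarithmic CV path with warm starts (default 30 values). The path runs
at a relaxed tolerance (1e-5) because the CV curve is flat at that
scale; the final fit at the chosen λ uses 1e-8. The intercept is handled
by centring and never penalized.

## Clustering

Gene blocks are found by k-means over variables: the p columns of the
(by default autoscaled) matrix are points in n-dimensional genome space.
The implementation is Lloyd's algorithm with k-means++ seeding from an
explicit seed, assignment ties broken to the lowest cluster index,
deterministic empty-cluster repair (reseed at the point farthest from
its current centre, iterated since a repair can empty the donor
cluster), and best-of-10 restarts by WSS. The number of blocks is chosen
on a grid by maximizing the mean silhouette index — the standard
convention that larger silhouettes indicate better-defined clusters —
with the total within-cluster sum of squares reported as an elbow
diagnostic. Singleton clusters contribute 0 to the silhouette.

## Synthetic data generator

The generator emulates the structural features of a blocked genotype
matrix that drive the method: p variables in K blocks with
compound-symmetric correlation w inside blocks and a constant weaker
correlation b between blocks (positive definite whenever
0 ≤ b ≤ w < 1); columns drawn as X = Z L' from the Cholesky factor of
the full correlation matrix, hence exactly unit variance in population;
a sparse coefficient vector with ⌈ρ·p_k⌉ nonzero entries per active
block drawn from U(0.5, 1.5) (positive, so within-block signals add);
and y = Xβ + ε with ε ~ N(0, σ²). The noise can alternatively be set
through the analytic signal-to-noise ratio β'Σβ/σ². All draws flow from
one seed; replicate seeds are spawned from a root sequence so individual
replicates are independently reproducible.

What the generator does **not** emulate: heavy-tailed or discrete
genotype scores, heteroscedastic phenotype noise, linkage-style local
correlation decay, and blocks of strongly unequal size. Passing tests on
this generator therefore demonstrate correctness of the algorithms and
their selection behaviour under the stated Gaussian block model, not
performance guarantees on real genotype data.

Defaults: K = 6 blocks of 20 variables, ρ = 0.2, within-block
correlation 0.5, between-block 0.2, σ² = 1, n = 100. The benchmark grid
reuses the published comparison axes — n ∈ {100…300}, sparsity
15–25 %, correlation 0.5–0.9 (used as the within-block value with half
of it between blocks) — with this package's own block layout and
coefficient/noise defaults, since those were open design choices. The
benchmark scenarios concentrate the signal in a single active block:
that is the regime block-selection statistics are designed for, and with
BwIP scaling as BIP/p_c a diffuse-signal design would make every
selection method discard true signal by construction. Benchmark results
are therefore read as orderings between methods under concentrated block
signal, never as absolute error levels. Problem sizes in the shipped
studies (50-replicate power runs, 10–50-replicate benchmark cells,
5-fold CV inside replicates) were chosen to keep the full study
reproducible on a single CPU in minutes.

## Numerical choices and limitations

- Autoscaling uses the n−1 denominator throughout (chemometrics
  convention); scale/centre round-trips are exact to ~1e-12.
- Degeneracy tolerance 1e-12 on squared norms; CV component grids are
  capped at min(max_components, n_train − 1, p).
- Ties in CV argmin go to the smaller component count (or larger
  penalty for the lasso path) — the parsimonious side.
- The prefilter removes columns with any missing value or variance not
  exceeding the cutoff (default 0, i.e. constants only); "low variance"
  has no universal threshold, so it is exposed as a knob.
- Multi-phenotype files are modelled one response at a time; there is no
  PLS2 path.
- Determinism: every stochastic step takes an explicit seed; runs are
  single-process, and CLI artifacts embed the resolved configuration and
  its hash.
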