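# Methods

This note documents the statistical procedures implemented in `phyloccur`,
the numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the package's known limitations.

## Composites

Traits enter the occurrence model through two principal-component scores.
The six analysis variables are maximum height, midpoint leaf length and
width ((min+max)/2 — ranges are routinely recorded for leaves, usually only
maxima for the other organs), maximum fruit size, and maximum calyx and
corolla length. Each column is natural-log transformed and z-scored with the
sample (n−1) standard deviation; the log base is irrelevant after
standardization but is fixed for score reproducibility. The PCA is computed
by SVD of the centered standardized matrix, i.e. on the correlation matrix;
loadings are unit-norm right singular vectors and `var_explained` is the
squared-singular-value fraction over all axes.

Principal-component signs are arbitrary, so each axis carries an
*orientation anchor* — a variable forced to load positively. Defaults:
axis 1 anchored on midpoint leaf length (scores grow with leaf/fruit size),
axis 2 on calyx length (scores grow with flower size, against height), and
the environment axis on ultramafic cover (scores grow with stress). Anchors
make the decomposition deterministic under row permutation and are
configurable.

The environment axis uses the same machinery on the three area variables
(z-scored, not logged — two are percentages and one is rainfall, none
log-dispersed across areas) and keeps only PC1.

## Spatial eigenvector

Inter-area distance is controlled by a single Moran eigenvector map (MEM)
pattern. Great-circle distances use the haversine formula with Earth radius
6371.0088 km (fixed for bit-reproducibility). The Gabriel condition —
edge (i,j) iff d(i,j)² ≤ d(i,k)² + d(j,k)² for every third point k — is
evaluated directly on great-circle distances rather than a planar
projection, because an archipelago spanning tens of degrees of longitude has
no faithful plane. The MEM basis diagonalizes Ω = H W H (H the centering
projector, W the binary adjacency), computed on an explicit orthonormal
basis of the centered subspace so the m−1 returned columns are exactly
zero-sum and orthonormal; Moran's I of column j is (m/S0)·λ_j.

Two genuinely open choices are documented as configuration rather than
guessed silently:

- *Connectivity weights*: the default decomposes the binary (unweighted)
  Gabriel adjacency, the standard MEM construction; a `distance` variant
  decomposing −½·H D² H (classical PCoA of the distance matrix) is provided.
- *Selection*: the "first" eigenvector is the one with the largest
  eigenvalue — the broadest positive-autocorrelation gradient — with no
  significance-based forward selection. If no eigenvalue is positive the
  selection still returns the largest, with a warning.

## Phylogenetic covariance

Species present in the data but absent from the tree are grafted beside a
congener: a congener tip is chosen uniformly at random (previously grafted
tips included), and the new species attaches at a uniform point along that
tip's terminal branch, the new tip's length equal to the attachment height.
This keeps the tree bifurcating, preserves contemporaneous tips on
ultrametric trees, and is deterministic given the seed. Attachment along the
terminal branch (rather than building a genus-crown polytomy) is the
simplest scheme that respects genus membership; the attachment-depth
distribution is a documented choice, not an estimate.

The Brownian covariance Σ has entries equal to shared root-to-MRCA branch
length and is divided by its maximum diagonal entry, giving unit diagonal
for ultrametric trees. The absolute height scale is thereby absorbed into
the phylogenetic variance σ_b², which should be read relative to this
normalization. Zero-length branches are permitted (they arise from polytomy
resolution in external trees).

## The occurrence model and PQL

The model is a Bernoulli GLMM with logit link, fixed effects
{intercept, pc1, pc2, stress, θ, pc1×stress, pc2×stress, pc1×θ, pc2×θ},
and two species-level random effects: an exchangeable effect a ~ N(0, σ_a²I)
and a phylogenetic effect b ~ N(0, σ_b²Σ). The compact statement of the
model lists only the interaction terms, but the estimated quantities include
the main effects; the default design therefore carries all nine columns and
`include_main_effects=False` reproduces the interaction-only form.

Fitting is penalized quasi-likelihood: iterate (1) linearize the Bernoulli
likelihood at the current η into working response z and weights
W = diag(μ(1−μ)); (2) update (σ_a², σ_b²) by REML of the working linear
model; (3) update β by GLS and the conditional modes by
C Zᵀ V⁻¹ (z − Xβ) with C = σ_a²I + σ_b²Σ and V = W⁻¹ + ZCZᵀ; stop when the
largest change in coefficients and variances is below `tol`. All solves use
the Woodbury identity, so the per-iteration cost is O(n³) in the number of
species, not O(N³) in observations.

Numerical choices (all in `PGLMMControl`):

- Variance optimization: Nelder-Mead on log(σ²+ε) with bound constraints
  [0, 10], two extra starting points (0.1, 1.0) on the first outer
  iteration and warm starts afterwards; `maxfev` 200.
- Convergence: max absolute parameter change < 1e-6, at most 50 outer
  iterations; non-convergence returns a result flagged `converged=False`
  with a warning rather than raising.
- μ is clipped to [1e-10, 1−1e-10], which caps the working weights under
  separation; a separated covariate yields large but finite coefficients
  and a non-convergence warning.
- With Σ = I the two variance components are exchangeable — only their sum
  is identified. The fit stays bounded (the REML surface is flat along the
  ridge); the reported split between σ_a² and σ_b² is then arbitrary, which
  is tested but not "fixed".
- Setting both variances to zero reduces the scheme exactly to IRLS, i.e.
  ordinary logistic regression; this is the package's strongest exactness
  anchor and is tested against an independent implementation at 1e-6.

PQL is a linearization and is biased toward zero for binary data with large
random-effect variances; on a 4-species instance its coefficients are
checked against maximum likelihood computed by tensor Gauss-Hermite
integration and agree to well under 0.15 at the variances used here
(σ² ≤ ~0.5). Wald z = estimate/SE with two-sided normal p values is used
throughout, matching the ensemble's averaging convention.

## Rarefied ensemble

Each of the 25 iterations draws one global species subset of size equal to
the minimum area richness and refits across all areas. (The alternative
reading — drawing a separate community per area — is noted as plausible but
not implemented; the global-subset reading matches the protocol of fitting
"25 separate models each with a randomly selected number of species".)
Composite scores, θ and the imputed tree are computed once on the full data
and subset afterwards; each subset's Σ is rescaled to unit maximum diagonal.
Iteration t uses seed `base_seed + t` and samples from the *sorted* species
pool, so results are invariant to input row order. Significance is declared
when the across-iteration mean Wald p is below 0.05, with no multiplicity
correction (matching the protocol being reproduced). Species never sampled
get an NaN prediction and a recorded count of zero — values are never
fabricated.

## Synthetic data generator

The generator emulates the structure the analysis assumes, with defaults
chosen as the package's standard study conditions:

- **Tree**: Yule process, n = 200 tips, scaled to unit height; genera are
  assigned by cutting the tree at half its height, so congeneric imputation
  is exercised realistically.
- **Traits**: correlated Brownian motion on the log scale (matrix-normal
  with row covariance Σ and a 6×6 rate matrix whose correlation blocks
  mirror the empirical pattern: leaf/fruit sizes covary, calyx/corolla
  covary and oppose height; log-scale SD 0.7 per trait over unit height —
  about a two-fold typical spread). Simulating on the log scale means the
  pipeline's log/z-score step is exercised honestly.
- **Areas**: m = 9 centroids on a lon/lat arc spanning ~55° of longitude;
  a latent gradient peaking at the archipelago center drives ultramafic
  cover up and rainfall/lowland down, plus independent noise (SD 0.3 on the
  standardized scale). With the noise at zero the three variables are
  exactly rank-1 and the stress axis explains 100% of their variance.
- **Occurrence**: drawn from the model itself. Effects are parameterized on
  the *design scale* — the PC scores the model actually sees — which avoids
  the circularity of specifying effects on raw traits and then comparing
  against coefficients of estimated axes. Defaults: intercept −0.5,
  pc1 −0.5, pc1×stress −0.3, all else zero; σ_a² = 0.1, σ_b² = 0.25.
  Species occurring nowhere are redrawn up to 50 times, then dropped and
  logged (real datasets contain no all-absent species by construction).

What the generator does *not* emulate: real geology or climate fields (the
environment is a one-dimensional gradient plus noise), observation effort or
detection error, island-size effects on richness, speciation/extinction
dynamics within the archipelago, and trait-dependent dispersal mechanisms.
Passing tests therefore demonstrate that the pipeline recovers the
generating process when its assumptions hold — not that those assumptions
hold for any particular flora.

## Validation problem sizes

The test suite validates the machinery at sizes chosen to give tight Monte
Carlo behavior while remaining quick to rerun: the logistic-regression limit
on 500 observations; the integrated-likelihood oracle on 4 species × 3 areas
(Gauss-Hermite, 15 nodes per dimension); parameter recovery over 40
replicates at 200 species × 12 areas (sign recovery ≥ 90%, mean bias
< 0.15); and ensemble type-I calibration over 50 replicates of the full
25-iteration protocol at 120 species × 9 areas (per-coefficient false-call
rate ≤ 10%). The acceptance script reruns the same computations at 20 and
15 replicates respectively.

## Known limitations

- PQL underestimates large random-effect variances for binary data; the
  package targets the moderate-signal regime (σ² ≲ 1 after unit-height
  scaling) validated by its oracles.
- The MEM selection uses no hypothesis test; when several eigenvalues are
  comparable the "first" pattern is a modeling choice.
- Congeneric imputation requires at least one congener tip; species from
  genera entirely absent from the tree are rejected rather than placed.
- The checks against the published Malesian analysis that depend on the
  deposited trait/area tables require those tables to be supplied locally
  (`data/deposited/`); without them the package validates against its own
  generative model only.
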