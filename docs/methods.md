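# Methods

`spatsim` simulates spatially resolved transcriptomics (SRT) data with
known ground truth. The pipeline decouples *what cells express* from
*where cells sit*: a generative model of expression is trained on a
labeled single-cell (or spot) dataset, and spatial coordinates are
synthesized either by mapping generated cells onto a real spatial
reference or by constructing patterns from scratch. Aggregating the
placed cells into platform-style capture spots yields benchmarking data
whose per-spot cell-type composition, per-gene spatial expression, and
domain labels are exactly known.

## Expression generation

A variational autoencoder is trained on all cells of the input
`ExpressionDataset` (non-negative, library-size + log1p normalized;
cells x genes). Encoder and decoder are four-layer MLPs — encoder widths
2048/1024/512/256 with ReLU after every layer except the last, linear
heads for the posterior mean mu and log-variance; decoder widths
512/1024/2048/k with ReLU after every layer *including* the output, so
generated expression is non-negative by construction. The latent space
has 128 dimensions. The training objective is the negative evidence
lower bound with a Gaussian observation model on normalized expression
(squared-error reconstruction, unit observation variance) plus the
analytic KL divergence between the diagonal-Gaussian posterior
`q(z|x) = N(mu, diag(sigma^2))` and the standard-normal prior,
`0.5 * sum(mu^2 + sigma^2 - 1 - log sigma^2)`. Sampling uses the
reparameterization `z = mu + sigma * eps`, one Monte-Carlo draw per
datum per step. Optimization is Adam (lr 1e-3, batch 128, default 200
epochs), implemented directly on NumPy arrays; everything is seeded and
single-CPU.

Population conditioning is post hoc: after training, the encoder means
of each population's cells are summarized by a diagonal Gaussian in
latent space; generating `count` cells of a population samples z from
that Gaussian and decodes. A population with a single cell gets unit
latent variance and a warning.

Numerical choices that matter on small inputs (a few hundred cells):

- **KL warm-up.** The KL weight ramps linearly from 0 to 1 over the
  first half of training (`kl_warmup_frac = 0.5`). Without it the
  posterior collapses and the decoder emits the global mean.
- **Informative-start initialization.** The log-variance head's bias
  starts at -4 (posterior sd ~0.14), so early training behaves like a
  plain autoencoder and the latent code becomes informative before the
  KL pressure arrives; the decoder output layer starts with 0.1-scaled
  weights and bias equal to the per-gene data mean, so the output ReLU
  does not start (and stay) dead.
- Log-variances are clipped to [-15, 15]; sigma is parameterized as
  `exp(0.5 * logvar)` for positivity.

## Reference-based spatial patterns

For each group `g` in a `SpatialReference` (coordinates + group labels +
expression), the model generates as many cells of population `g` as the
reference has positions in `g`. The cost matrix is the squared Euclidean
distance between generated and reference expression on the shared gene
set (an error is raised below 10 shared genes), and the exact optimal
transport problem `argmin <gamma, M>` with uniform marginals is solved —
via the assignment reduction for the square/uniform case (a permutation
vertex of the Birkhoff polytope is optimal) and the HiGHS LP solver for
general marginals. "Maximum likelihood of spatial origin" is made
concrete as a deterministic greedy bijection: repeatedly take the
largest remaining entry of the plan, fix that (cell, position) pair,
delete its row and column; ties break toward the lowest (row, column)
index. The mapping never sees reference coordinates — only expression —
so group geometry in the output is inherited from the reference, not
imposed.

## Reference-free spatial patterns

**Random patterns.** The unit square (or cube, for 3-D) is divided into
`grid_n` grids per axis and a Gaussian random field `V ~ MVN(0, Sigma)`
is drawn over grid centers with squared-exponential covariance
`Sigma_ij = exp(-(D_ij/delta)^2)`, `D` the Euclidean distance matrix in
grid units (adjacent centers at distance 1). Sampling uses a Cholesky
factor with escalating jitter (from 1e-8). A larger autocorrelation
length `delta` gives more connected patterns. Each patterned population,
in declared order, claims the `round(q * grid_n^dim)` still-unclaimed
grids ranked highest by a fresh field draw, where `q` is its cell
proportion; its cells are placed uniformly inside claimed grids, and
unpatterned populations spread over leftover grids. The exact mechanism
linking the field to grid selection is a design choice of this package:
ranking by field value reproduces delta-controlled connectivity while
honoring population proportions exactly. A clarity parameter `lambda` in
[0, 1] then swaps the coordinates of exactly `round((1-lambda) * N)`
cells, paired uniformly at random (an odd participant is dropped), which
blurs patterns without changing the coordinate multiset or any label.

Measured behavior (recomputed by `scripts/acceptance.py`): the mean
Moran's I of patterned populations is monotone increasing over
delta in {0.5, 1, 2, 5} and monotone decreasing as lambda falls 1 -> 0,
and exceeds that of unpatterned populations.

**Customized patterns.** Four basis kinds label positions scattered
uniformly over the canvas:

- *mixed*: positions sampled to user proportions, no geometry;
- *cluster*: rotated-ellipse interior, `x_r^2/a^2 + y_r^2/b^2 < 1` after
  translating to the center and rotating by the direction angle
  (strict inequality; the boundary, a measure-zero set, is outside);
- *ring*: annulus between the (a, b) ellipse and the widened
  (a+d, b+d) ellipse; a second width extends to double rings, and the
  enclosed disc can optionally carry its own population;
- *vessel*: stripe of width d around the segment between two endpoints,
  via projections u (along) and v (perpendicular) measured from the
  offset reference point `(x1 + d*p_x/2, y1 + d*p_y/2)` with `p` the unit
  perpendicular; inside iff `0 <= u <= l` and `|v| <= d/2`. The offset
  reference places the stripe on one side of the endpoint segment; a
  `symmetric` flag recenters it on the segment for users who want the
  endpoints to be the stripe's axis.

Member positions get the pattern's population except a user-set
infiltration fraction reassigned i.i.d. to infiltrating populations;
non-members get the background. Patterns compose in painter's order
(later specs overwrite earlier labels where their geometry claims a
position). Pattern synthesis decides the *layout*; expression is paired
per label downstream (e.g. by generating that many cells per
population).

## Spot assembly

Cells are aggregated into spots whose spacing comes from a target
average of `n` cells per spot and the local cell density: square grids
(spacing `sqrt(n/density)`, canvas tiled exactly with the nearest
integer tile count), hexagonal lattices (equal per-spot catchment area,
six equidistant neighbors for interior spots), or uniform random centers
(one per `n/density` of area). Cells attach to their containing tile
(square/hex — for hexagons the tile is the Voronoi cell of the center)
or nearest center (random); boundary ties go to the lower-index tile.
Spot expression is the exact sum of member rows, the composition row is
the member population proportions (sums to 1 by construction), and empty
spots are dropped, as real platforms report only tissue-covered spots.
Platform presets mirror realized averages of 2.34 (random/Slide-seq-like),
10.5 (hexagonal/Visium-like) and 34.01 (square/ST-like) cells per spot;
they are targets, not guarantees. A high-resolution square grid can be
merged in non-overlapping `factor x factor` blocks (a 33x33 grid merged
3x3 gives 121 spots from 1089), with expression summed and composition
re-derived from pooled members. 3-D assignments split into k equal-width
slices along any axis, each cell landing in exactly one slice. Targeted
gene panels are selected at random, by cross-cell variance (HVG), or by
per-population one-vs-rest mean log-expression difference taken
round-robin across populations (marker mode).

## Evaluation metrics

All metrics are implemented from first principles (the test suite checks
them against brute-force oracles and, for clustering metrics, against
scikit-learn):

- per-gene vectors: Pearson correlation and mean absolute error;
- composition vectors: Pearson, Spearman (Pearson of mid-ranks — equal
  to the classical `1 - 6 sum d^2 / n(n^2-1)` shortcut when tie-free),
  RMSE, and Jensen-Shannon divergence (inputs renormalized to sum 1,
  `0 log 0 = 0`, natural log so JS <= ln 2; the log base is switchable);
- rank aggregation: the accuracy score AS is the mean over the four
  composition metrics of the normalized rank `(m - r + 1)/m`, so the
  best of m methods scores exactly 1 and the worst `1/m`; ties get
  mid-ranks, which keeps AS invariant to monotone rescaling of any
  metric column;
- clustering agreement from the contingency table: adjusted Rand index
  (Hubert-Arabie), NMI normalized by the arithmetic mean of the label
  entropies, homogeneity `1 - H(C|K)/H(C)`, and Fowlkes-Mallows
  `sqrt(precision * recall)` over co-membership pairs with
  `recall = TP/(TP+FN)`;
- `pcc_gbm`: a regression-smoothed fidelity score — two
  coordinate-to-expression regressors (gradient-boosted trees, depth 3,
  100 rounds, seeded; the regressor is pluggable) are fitted on real and
  simulated data separately, both predict at the simulated coordinates,
  and the Pearson correlation of the predictions is returned; robust
  when the two datasets do not share positions;
- Moran's I with row-standardized k-nearest-neighbor weights (k = 6 by
  default; a precomputed weight matrix may be supplied). Constant
  vectors make correlations and Moran's I undefined; these return NaN so
  callers decide exclusion.

## Synthetic fixtures

`generate_fixture_scrnaseq` draws negative-binomial counts (mean m,
dispersion r; variance `m + m^2/r`, r = 0.5 by default) with per-gene
baseline means shared across populations, lognormal with sigma = 1.3
around a base mean of 1 — real atlases span orders of magnitude in
per-gene mean expression, and the wide spread makes much of the zero
pattern gene-structured rather than pure dropout. Each population's
block of 10 marker genes is multiplied by a fold change (default 5), and
counts pass through the same normalization as real inputs. Defaults give
3 populations x 100 cells x 100 genes with a zero fraction near 0.56.
`generate_fixture_reference` puts positions on a 30x30 grid with either
contiguous horizontal bands per population (a layered-cortex-style
reference) or painted elliptical blobs, expression drawn from the
matching population's count model.

What the fixtures emulate: population structure, marker signal,
realistic sparsity and mean-variance behavior. What they do not: batch
effects, doublets, ambient RNA, spatial gradients *within* a population,
platform noise (optics, diffusion, segmentation), or barcode artifacts.
Passing tests on fixtures therefore demonstrates correctness of the
machinery and recovery of planted structure, not performance on any real
tissue.

## Problem sizes and runtime choices

The shipped tests and the reproduction script train the VAE for 100
epochs on the 300-cell fixture (about a minute on one CPU), use 20
replicates for pattern-monotonicity statistics, 20,000 field draws for
the empirical covariance check, and a 20,000-cell canvas for the
resolution ladder so integer tile counts resolve the coarsest rung
(n = 100). The exact-LP transport solver is used throughout; an
entropic approximation is deliberately not shipped since all shipped
problem sizes are exact-solvable in well under a second.

## Known limitations

- **Sparsity of generated cells.** With a Gaussian observation model,
  the decoder's output is a conditional mean, which is positive for any
  gene that is expressed anywhere in a population; exact zeros are only
  reproduced where zeros are (nearly) population-deterministic. On the
  shipped fixture — whose zeros are per-cell dropout around shared
  baselines — reconstruction of training cells reproduces the zero
  fraction almost exactly, but fresh samples from the fitted latent
  Gaussian interpolate between memorized codes and are much denser than
  the training data (`vae_zero_fraction_gap` in the reproduction
  script's output quantifies this). On data whose zeros follow
  population expression programs, the same machinery preserves sparsity.
- Per-population latent summaries use diagonal covariance; correlations
  between latent dimensions within a population are discarded.
- The greedy plan-extraction bijection is one deterministic reading of
  "maximum-likelihood" assignment; per-position argmax (possibly
  non-bijective) is another and is not implemented.
- Hexagonal and random lattices target the requested cells-per-spot on
  average only; realized values drift near canvas edges.
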