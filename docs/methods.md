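# Methods

This note documents the model, its parameters and defaults, the synthetic
data generator, and the numerical and design choices behind `lncdis`.

## Problem setting

The task is link prediction on a heterogeneous biological network: given
binary association matrices `A` (lncRNA × disease), `A_lg` (lncRNA × gene)
and `A_gd` (gene × disease), plus per-entity side information (expression,
interaction profiles, an ontology), score every unobserved lncRNA-disease
pair. Observed associations are treated as reliable positives; unobserved
pairs are unlabeled, not negatives, which is why training samples a limited
number of zero entries rather than fitting the full zero sea.

## Similarity networks

**Biweight midcorrelation (LncSm1).** For expression vectors the package
uses the median/MAD-weighted correlation with tuning constant `c = 9`:
entries further than `9·MAD` from the median get zero weight, which makes
the coefficient robust to isolated outliers that distort the Pearson
correlation. When a profile's MAD is zero the biweights are undefined and
the implementation falls back to the Pearson coefficient for that pair,
logging the event. Bicor values lie in [−1, 1]; diffusion consumes their
absolute value (a random walk needs nonnegative weights), while the signed
matrix is preserved in the similarity output.

**Gaussian interaction-profile kernels (LncSm2, LncSm3, DisSm2).** For
binary interaction profiles `p_i`, similarity is
`exp(−α ‖p_i − p_j‖²)` with `α = α′ / ((1/N) Σ_i ‖p_i‖²)` and `α′ = 0.5`
for each profile type. Dividing by the mean squared profile norm makes the
kernel scale-stable in the typical number of interaction partners (a node
with many partners is not automatically dissimilar from everything); the
multiplicative variant is available as
`bandwidth_convention="multiply"` for comparison.

**Ontology semantic similarity (DisSm1).** Wang's DAG measure: each
disease term contributes S-values to its ancestors, decaying by a factor
of 0.5 per `is_a` edge (best path), and the similarity of two terms is the
shared S-mass divided by the sum of their total S-masses. It is symmetric,
in (0, 1], and exactly 1 on the diagonal. A precomputed similarity matrix
can be supplied instead of a DAG, so values computed by external ontology
tooling can be injected bit-exactly.

Any subset of the five networks may be present (missing-omics ablations);
at least one per entity type is required.

## Diffusion and fusion

Each similarity network `W` is column-normalised (random-walk convention)
and diffused by random walk with restart,
`p ← (1−r)·Ŵ·p + r·e_seed`, solved by power iteration to an L1 tolerance
of 1e-8 (max 10,000 iterations). The restart probability defaults to
`r = 0.7`, the common choice in biological network propagation; it is
configurable. Isolated nodes (all-zero columns) return their outgoing mass
to the seed so every stationary column sums to 1.

Within an entity type, node `i`'s stationary columns are concatenated
across member networks and the fused topological similarity is the cosine
between concatenated profiles (`fusion="mean"` averages the stationary
matrices instead). The result is symmetrised, clipped to [0, 1] against
floating-point drift, and its diagonal forced to 1.

## Embedding

Initial node representations (`d = 64` by default) are drawn i.i.d.
uniform(−0.5/d, 0.5/d) from the run seed. One aggregation layer computes,
for each node, relation-wise sums of ReLU-transformed neighbor
representations weighted by the **row-normalised** relation matrices, so
aggregated magnitudes are comparable across node degrees
(`neighbor_norm="none"` disables the normalisation). The lncRNA-gene and
gene-disease transforms are shared between the two directions of their
relation; the lncRNA-disease direction has separate transforms per side,
and each transform has its own bias. The concatenation of a node's own
representation with its aggregate (length 2d) passes through a single
shared ReLU layer into `d_low = 32` dimensions and is L2-normalised to a
unit vector. A node whose projection is entirely non-positive would have
zero norm; an ε = 1e-12 floor keeps the embedding finite and deterministic
(re-randomising was rejected because it breaks seed-reproducibility), and
the event is logged.

## Reconstruction objective and training

Five bilinear decoders reconstruct the observed blocks from embeddings:
cross-type blocks use two mapping matrices (`E₁ E₂ᵀ`, each
`d_low × q`, `q = d_low` by default), within-type blocks use `E Eᵀ`, which
makes the reconstructed LTS/DTS blocks exactly symmetric for any
parameters. The loss is the plain sum of squared errors over:

* the A block restricted to a training mask (all observed positives plus
  `negative_sampling_ratio = 1.0` times as many uniformly sampled zeros);
* the dense LTS and DTS blocks in full;
* the A_lg and A_gd blocks restricted to masks built the same way as A's.

Masking every sparse binary block (rather than only A) keeps the
736-positive gene matrices from acting purely as shrinkage pressure: with
full-matrix sums, their ~47k zero entries dominate the gradient and the
informative positives are drowned. `loss_mask="full"` restores the
full-matrix reading for comparison.

Embeddings are recomputed from the current parameters at every iteration,
so embedding parameters, transforms and decoders are trained end-to-end.
Gradients are exact for the composite bilinear/ReLU/normalisation graph
(subgradient 0 at ReLU kinks), verified against central finite differences.
The optimiser is full-batch gradient descent with a backtracking line
search: each iteration's trial step is twice the previously accepted step
(capped at `learning_rate = 0.01`) and is halved until the loss decreases,
which makes the loss trace non-increasing and removes the need to tune the
step to the loss scale. Training stops when the relative loss change drops
below `convergence_tol = 1e-6` or after `max_iterations` (2000 by default;
the canned experiments use 1000, which is past the point where held-out
accuracy stops improving at the default network scale). A loss above 1e12
aborts with a divergence error.

Scores for ranking are the A-block reconstruction itself, so the score
matrix has rank at most `min(d_low, q)`.

## Evaluation protocols

* **ROC/AUC**: rank-based with ties counted 0.5 (Mann–Whitney); the curve
  steps through grouped score thresholds so its trapezoidal integral equals
  the U-statistic exactly.
* **LOOCV**: every known pair is withheld once; the model is retrained with
  that entry zeroed and excluded from negative sampling, and the held-out
  lncRNA is ranked against the disease's candidates. The default warm-start
  mode re-runs up to 200 iterations from the parameters converged on the
  full data — same convergence target as retraining from scratch at a
  fraction of the cost (`mode="full"` retrains from scratch). An optional
  audit trail records, per evaluation, the held-out entry's value in the
  training matrix and its absence from the loss mask.
* **Random-split stability**: the known associations are split
  train/test (default 2/3 train) `n_splits` times, split `s` seeded
  `seed + s`; per-split AUCs are summarised by the five-number summary
  (min, Q1, median, Q3, max).
* **Label corruption**: `round(fraction · m·n)` entries of A, chosen
  uniformly over all cells, are flipped 1↔0 — at 10% corruption the flips
  are overwhelmingly spurious positives, a much harsher regime than
  removing true links.

## Synthetic data generator

The generator plants rank-`r` structure (default `r = 4`): latent factors
`U` (lncRNA), `V` (disease), `G` (gene) are i.i.d. standard normal, and
each association matrix is the exact top-`count` thresholding of the
corresponding factor product (2169 / 736 / 462 ones at the default
356/354/132 scale). Expression is a linear read-out of the latent factors
plus Gaussian noise (`noise_sd = 0.1`); binary interaction profiles are
Bernoulli draws with a logistic link on latent affinity whose intercept is
solved numerically to hit the target density (8%); the ontology is a
binary tree from average-linkage clustering of the disease factors, so
ontologically close diseases are latent-similar.

Measured omics views (expression, profiles, ontology) observe only the
leading `observed_rank = r/2` latent components, while the association
matrices use all `r`. This mirrors real multi-omics data, where similarity
measurements are noisy, partial proxies of function and relational gene
evidence carries complementary information — and it is what makes the
gene-ablation experiment meaningful: with fully shared factors every view
is redundant and removing one cannot hurt.

What the generator does **not** emulate: hub/degree heterogeneity and
block community structure of curated databases, ascertainment bias
(well-studied lncRNAs have more recorded links), non-linear latent
effects, and ontology annotation errors. Passing the recovery experiments
therefore shows the pipeline can extract planted low-rank signal through
its own similarity/diffusion/embedding machinery under controlled
violations (noise, label flips, missing views) — not that real-database
accuracy will match.

## Study conditions for the canned experiments

`lncdis.experiments` fixes the validation conditions: the default-scale
generator, 20% of A's positives held out (with matched negatives, both
excluded from training), training to `max_iterations = 1000`, five seeds.
Conditions: default, noiseless (`noise_sd = 0`), gene-block ablation, and
10% label corruption of the training matrix (evaluation pairs stay clean).
`scripts/acceptance.py` reports the resulting held-out AUCs and deltas.

## Known limitations

* Full-batch gradients make training O(m² d_low) per iteration; desk-scale
  networks (hundreds to a few thousand nodes) are the intended regime.
* The loss is non-convex; different seeds converge to different optima and
  per-seed held-out AUC varies by a few points. Canned experiments average
  over five seeds.
* The warm-start LOOCV reuses parameters fitted with the held-out pair
  present; the subsequent masked re-optimisation removes its influence on
  the objective, but a residual imprint in the non-convex landscape cannot
  be excluded. `mode="full"` is the conservative alternative.
* Wang similarity is computed over all disease pairs (O(n²) ancestor-set
  intersections); adequate for hundreds of diseases, slow beyond that.
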