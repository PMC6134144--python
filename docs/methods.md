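# Methods

`cellspring` embeds single-cell expression profiles in the plane so that a
user-supplied clustering appears as compact groups connected along
differentiation trajectories, and quantifies whether one cluster is a
transition state between two others. This note records the model, the
numerical choices, and what the synthetic benchmarks do and do not show.

## Model

### Input and pre-processing

The input is a genes × cells matrix of non-negative integer counts (UMIs)
plus one class label per cell (the prior clustering). Four pre-processing
stages run in fixed order:

1. **Class filtering** removes clusters smaller than `min_class_size`
   (default 5) and their cells; at least two classes must survive.
2. **UMI normalization** divides each cell by its total count and rescales
   by the median of the original per-cell totals, so values stay count-like
   (the rescale keeps magnitudes stable for the SGD classifier used next).
3. **Feature selection** (optional) is recursive feature elimination under
   a linear hinge-loss classifier trained by SGD with L2 regularization,
   one-vs-all across classes. Each round removes the `rfe_step` (default
   20) genes with the smallest importance, where a gene's importance is the
   L2 norm of its weights across the per-class models, and records
   stratified 5-fold CV accuracy. Elimination stops when accuracy has
   failed to beat the best observed for two consecutive rounds (one round
   of patience); the best-scoring gene set is returned. One seed governs
   both SGD shuffling and fold assignment, making the stage reproducible.
4. **Correlation transform** re-describes cell *i* by its vector of Pearson
   correlations to every cell (over the selected genes), p_i ∈ [−1,1]^n.
   Similarity then depends only on the shape of the expression pattern;
   the transform is invariant to per-cell affine rescaling.

### Instance graph

All distances are Euclidean in the correlation profile space. Density is
D(p_i) = mean_j cos(p_i, p_j), the average cosine similarity of a cell to
all cells (self included) — a normalized, outlier-robust density proxy.
Two edge types are built:

* **knn edges**: each cell connects to its `k` (default 3) nearest
  neighbors of the *same* class; desired length = the pairwise distance.
* **shift edges**: each cell connects to its `k'` (default 1) nearest
  neighbors that are *denser* and of a *different* class, restricted to the
  cell's `h` nearest neighbors overall (the knn horizon, default 10·k').
  This is quick-shift-style mode seeking: differentiation trajectories
  ascend the density gradient from mature cells toward progenitors, and
  the horizon keeps the links local. "Denser" is strict; ties in distance
  break toward the lower cell index for determinism.

A confidence parameter C ≥ 0 contracts every knn desired length to
d/(1+C), magnifying class separation (C = 1…9 gives two- to ten-fold
contraction) without changing the graph topology; shift edges are
untouched. C = 0 is the identity.

### Layout

Desired distances d_ij for *all* pairs are weighted shortest paths on the
instance graph (Dijkstra, edge weight = desired length). Springs with
strength k_ij = K/d_ij² (K = 1; it only scales the energy, not the argmin)
define the energy E = Σ_{i<j} ½ k_ij (|v_i − v_j| − d_ij)². Minimization
moves one particle at a time: the particle with the largest gradient
magnitude Δ_m is relaxed by a 2-D Newton–Raphson iteration on its (x, y)
(up to 50 inner steps), and the process repeats until max_m Δ_m < tol
(default 1e-4) or `100·n` particle selections. Implementation notes:

* Particles start on a regular n-polygon of radius max d_ij / 2, in input
  order; the starting position is not critical for the minimum reached.
* A Newton step that would raise the particle's energy is replaced by a
  backtracking line search along the Newton direction (then the gradient
  direction); only energy-decreasing positions are accepted, so the energy
  trace over accepted moves is non-increasing by construction — the raw
  Newton method does not guarantee this.
* A (near-)singular 2×2 Newton system falls back to a diagonally scaled
  gradient step.
* Per-particle gradients are cached and updated incrementally (O(n) per
  accepted move), so the argmax selection does not cost O(n²) per
  iteration; this matters at a few hundred cells.
* Disconnected graphs are laid out per connected component and the
  components packed on a grid with margins proportional to their bounding
  boxes; a single-vertex component is a point.

### Transition scoring

For a cluster triplet, training is restricted to cells of the three
classes. Each cell gets an out-of-fold probability triple from one-vs-rest
L2-regularized logistic regression (liblinear, C = 1, stratified 5-fold
CV; one binary model per class per fold), renormalized to sum to 1 — the
renormalization is needed because independent OvR probabilities do not lie
on the simplex. Triples are drawn in the unit-side equilateral triangle at

    ( ½ (2b + c)/(a+b+c),  (√3/2) c/(a+b+c) ),

so a = 100% sits at (0,0), b at (1,0), c at (½, √3/2). Class-averaged
probabilities form the 3×3 confusion matrix D (row r = mean triple over
cells truly in class r); D is symmetrized as D' = (D + Dᵀ)/2 and the
off-diagonals E = (D'₁₂, D'₁₃, D'₂₃) give the confusion score

    S = min(E) / (sum of the other two components),

which lies in [0, 0.5]: S is small when one class pair is cleanly
separated while both other pairs are confused — the signature of a
transition through the shared class — and 0.5 when all pairs are equally
confused. A transition is called when S is strictly below the threshold
(default 0.3). If the two larger error components are both zero the score
is degenerate (perfectly separated triplet) and reported as 0 with a flag
rather than NaN. An alternative symmetrization D·Dᵀ/2 is available as a
config switch for comparison; the averaged form is the default because it
keeps the off-diagonals interpretable as pairwise error rates and gives
S = 0.5 exactly for the uniform matrix.

## Synthetic benchmark data

The generator produces the geometry the method relies on, with ground
truth attached, and nothing more:

* Cluster centroids sit on a lineage tree in a latent space where each
  tree segment (and the root) activates its own disjoint module of
  informative genes. Module activations accumulate along the path from the
  root and the accumulated signature is normalized onto a sphere of radius
  √2·branch_length. Chordal centroid distance is then non-decreasing in
  tree distance (with occasional exact ties), and all clusters share the
  same signature magnitude, so density differences come from spread, not
  from signature size.
* Within-cluster spread is isotropic Gaussian, growing linearly with tree
  depth from `within_cluster_sd` (default 0.25) at the root to
  `density_gradient` × that (default 1.5×) at the deepest leaf —
  progenitors are tighter, hence denser, as in real differentiation data.
* A `bridge_fraction` (default 0.15) of each parent's cells is placed
  along the first half of parent→child segments and labeled with the
  parent: differentiating intermediates at class borders.
* Latent coordinates are shifted, scaled and rounded onto a non-negative
  integer count scale (offset 10, scale 10), with the remaining genes
  i.i.d. baseline noise (sd 0.3 on the latent scale). The affine map
  preserves the latent Pearson geometry exactly; an exponential map was
  rejected because it distorts correlations between distant clusters.
* Defaults: 5 clusters in a linear chain, 60 cells each, 200 genes, 30
  informative. The unordered-triplet generator places three clusters on an
  equilateral triangle with spread = overlap × side (default overlap 0.5),
  giving symmetric pairwise confusion with no ordering.

What this does **not** model: dropout, over-dispersion, library-size
variation beyond a scalar, batch effects, doublets. Passing benchmarks
therefore show that the pipeline recovers trajectory structure when the
correlation geometry carries it; they do not certify performance under
realistic scRNA-seq noise.

## Benchmark protocol and problem sizes

The end-to-end trajectory benchmark runs the full pipeline (feature
selection on, correlation transform, k = 3, k' = 1, h = 10, C = 1) on the
default 5×60-cell lineage over 10 seeded replicates and measures: the
fraction of truth-adjacent cluster pairs joined by at least one shift
edge; whether any shift edge joins clusters at tree distance ≥ 3; and
whether the cluster centroids in the layout order along the principal axis
as in the chain. The three conditions jointly hold in at least 9 of 10
replicates. The transition benchmark compares the confusion score of a
generated linear A→B→C lineage against a matched unordered triplet over 10
replicates (the linear score is lower in all of them; typical values
≈ 0.11 vs ≈ 0.44). These sizes keep a full benchmark run at a few minutes
on one CPU while leaving the per-replicate n (300 cells) large enough for
stable density estimates.

## Known limitations

* Exact nearest-neighbor computation only (O(n²) distances); intended for
  up to a few thousand cells, as in typical sorted-population datasets.
* The layout optimizer finds a local minimum; different input orders can
  reach different (rigid-motion-inequivalent) layouts of similar energy.
  Given a fixed input order and configuration it is fully deterministic.
* Class labels are trusted input: wrong or too-coarse clusterings yield
  misleading layouts (a class that naturally splits shows up as separate
  contracted groups).
* The confusion score is defined for exactly three classes; larger simplex
  generalizations are out of scope.
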