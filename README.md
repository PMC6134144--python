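# cellspring

Class-informed force-directed embedding of single-cell expression data.

Clustering of scRNA-seq profiles identifies cell types, but the discrete
labels hide the continuous differentiation processes connecting them.
`cellspring` takes a count matrix **and** a user-supplied cluster
assignment and produces a 2-D layout in which clusters appear as compact
groups *and* differentiation trajectories appear as chains of clusters
connected along density gradients — plus a quantitative test for whether
one cluster is a transition state between two others.

## The method

Cells are re-described by their Pearson correlation to every cell (after
class filtering, library-size normalization and optional recursive feature
elimination), and a graph is built with two edge types:

* **knn edges** — each cell to its *k* nearest *same-class* neighbors:
  pulls classes into compact groups. A confidence value *C* contracts
  their desired lengths to d/(1+C), magnifying class separation without
  changing the graph.
* **shift edges** — each cell to its *k′* nearest neighbors that are
  **denser** (density = mean cosine similarity to all cells) and of a
  **different class**, within the cell's *h* nearest neighbors: quick-shift
  style mode seeking that traces differentiation paths from mature cells
  up the density gradient toward progenitors.

The layout minimizes the Kamada–Kawai spring energy

$$E = \sum_{i<j} \tfrac12 k_{ij}\,(|v_i - v_j| - d_{ij})^2,
\qquad k_{ij} = K/d_{ij}^2,$$

where d_ij is the shortest-path distance on the graph, by moving one
particle at a time (the one with the largest gradient) with a 2-D
Newton–Raphson step. For a cluster triplet, out-of-fold one-vs-rest
logistic probabilities are plotted on the probability simplex and condensed
into a **confusion score** S = min(E)/(sum of the other two pairwise
errors) ∈ [0, 0.5]: small S means one class pair is cleanly separated
while both other pairs are confused — the signature of a transition
through the shared class.

See `docs/methods.md` for assumptions, defaults and numerical details.

## Worked example

```sh
python examples/embed_lineage.py
```

generates a synthetic 5-cluster lineage A→B→C→D→E with known ground truth,
runs the full pipeline and prints:

```
generated 300 cells x 200 genes, clusters ('A', 'B', 'C', 'D', 'E')
selected 160 genes, 658 knn + 119 shift edges, final layout energy 1035.1
shift edges between cluster pairs (truth: AB, BC, CD, DE):
  A-B: 4
  B-C: 16
  C-D: 36
  C-E: 7
  D-E: 56
```

All four truth-adjacent pairs are linked by shift edges (plus a handful
between C and E, two steps apart); no edge joins distant clusters. And

```sh
python examples/transition_scoring.py
```

contrasts a linear A→B→C lineage with a matched unordered triplet:

```
linear A->B->C: pairwise errors (0.088, 0.032, 0.150) -> S = 0.134 (transition)
unordered triplet: pairwise errors (0.219, 0.221, 0.216) -> S = 0.492 (no_transition)
```

The low score identifies B as a transition state; the symmetric triplet
sits near the maximal-confusion value 0.5. Other examples cover feature
selection (`examples/feature_selection.py`) and figure rendering
(`examples/render_figures.py`).

There is also a thin CLI:

```sh
cellspring simulate -o sim --topology A-B,B-C --seed 1
cellspring embed sim/matrix.tsv sim/classes.tsv -o out -k 3 -c 1
cellspring ternary sim/matrix.tsv sim/classes.tsv A B C -o tern
```

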