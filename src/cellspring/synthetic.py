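"""Synthetic branching-lineage expression data with known ground truth.

The generator emulates the geometry the method relies on in real
differentiation data: cluster centroids sit on a tree in expression space
(centroid distance grows with tree distance), progenitor (earlier) clusters
are denser than mature ones, a fraction of cells bridges parent->child
segments (differentiating intermediates), and values are count-like
non-negative integers.

It makes no attempt at realistic scRNA-seq noise (dropout, dispersion);
counts are produced by exponentiating and rounding Gaussian latent
coordinates, which is sufficient to exercise every formula in the pipeline
while keeping the geometry easy to reason about.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import ClassAssignment, ExpressionMatrix

_DEFAULT_TOPOLOGY = (("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"))


@dataclass(frozen=True)
class LineageSpec:
    """Parameters of a synthetic lineage.

    topology: tree as (parent, child) cluster pairs; the root is the unique
        parent that never appears as a child.
    n_per_cluster: cells per cluster (bridge cells included).
    n_genes / n_informative_genes: total genes and how many carry lineage
        signal (the rest are i.i.d. baseline noise).
    within_cluster_sd: latent Gaussian spread of the root cluster.
    bridge_fraction: share of each parent cluster's cells interpolated along
        its outgoing parent->child segments (labeled with the parent).
    density_gradient: leaf-to-root spread ratio (>= 1); larger values make
        progenitors tighter, hence denser.
    branch_length: latent distance between adjacent centroids.
    """

    topology: tuple[tuple[str, str], ...] = _DEFAULT_TOPOLOGY
    n_per_cluster: int = 60
    n_genes: int = 200
    n_informative_genes: int = 30
    within_cluster_sd: float = 0.25
    bridge_fraction: float = 0.15
    density_gradient: float = 1.5
    branch_length: float = 2.0
    noise_gene_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "topology", tuple((str(p), str(c)) for p, c in self.topology)
        )
        if self.n_per_cluster < 1 or self.n_genes < 1 or self.n_informative_genes < 1:
            raise ValueError("all counts must be positive")
        if self.n_informative_genes > self.n_genes:
            raise ValueError("n_informative_genes exceeds n_genes")
        if not (0 <= self.bridge_fraction < 1):
            raise ValueError("bridge_fraction must be in [0, 1)")
        if self.within_cluster_sd < 0 or self.noise_gene_sd < 0 \
                or self.branch_length <= 0:
            raise ValueError("spreads must be non-negative, branch_length positive")
        if self.density_gradient < 1:
            raise ValueError("density_gradient must be >= 1")
        _validate_tree(self.topology)

    @property
    def clusters(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p, c in self.topology:
            seen.setdefault(p, None)
            seen.setdefault(c, None)
        return tuple(seen)

    @property
    def root(self) -> str:
        children = {c for _, c in self.topology}
        roots = [n for n in self.clusters if n not in children]
        return roots[0]


def _validate_tree(topology: tuple[tuple[str, str], ...]) -> None:
    if not topology:
        raise ValueError("topology must contain at least one edge")
    nodes: set[str] = set()
    children: set[str] = set()
    for p, c in topology:
        if p == c:
            raise ValueError(f"self-edge {p!r}")
        nodes.update((p, c))
        if c in children:
            raise ValueError(f"cluster {c!r} has two parents")
        children.add(c)
    roots = nodes - children
    if len(roots) != 1:
        raise ValueError(f"topology must have exactly one root, found {sorted(roots)}")
    if len(topology) != len(nodes) - 1:
        raise ValueError("topology is not a tree")
    # connectivity: walk from the root
    adj: dict[str, list[str]] = {}
    for p, c in topology:
        adj.setdefault(p, []).append(c)
    stack, seen = [next(iter(roots))], set()
    while stack:
        node = stack.pop()
        seen.add(node)
        stack.extend(adj.get(node, []))
    if seen != nodes:
        raise ValueError("topology is not connected")


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated matrix + labels with the ground truth that produced them."""

    matrix: ExpressionMatrix
    classes: ClassAssignment
    truth_adjacency: frozenset[frozenset[str]]
    spec: LineageSpec | None = None
    centroids: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def _tree_depths(spec: LineageSpec) -> dict[str, int]:
    depth = {spec.root: 0}
    pending = list(spec.topology)
    while pending:
        remaining = []
        for p, c in pending:
            if p in depth:
                depth[c] = depth[p] + 1
            else:
                remaining.append((p, c))
        pending = remaining
    return depth


def tree_distances(spec: LineageSpec) -> dict[tuple[str, str], int]:
    """Unweighted tree distance between every cluster pair."""
    adj: dict[str, set[str]] = {}
    for p, c in spec.topology:
        adj.setdefault(p, set()).add(c)
        adj.setdefault(c, set()).add(p)
    dist: dict[tuple[str, str], int] = {}
    for start in spec.clusters:
        seen = {start: 0}
        frontier = [start]
        while frontier:
            nxt = []
            for node in frontier:
                for nb in adj[node]:
                    if nb not in seen:
                        seen[nb] = seen[node] + 1
                        nxt.append(nb)
            frontier = nxt
        for node, d in seen.items():
            dist[(start, node)] = d
    return dist


def _latent_to_counts(latent: np.ndarray, n_genes: int, rng: np.random.Generator,
                      noise_sd: float = 0.3, offset: float = 10.0,
                      scale: float = 10.0) -> np.ndarray:
    """Embed latent coordinates into the first dims of gene space, pad with
    baseline noise genes, and shift/scale/round onto a non-negative integer
    count scale.  The affine map keeps the latent Pearson geometry intact
    (correlations are location/scale free)."""
    n_cells, n_lat = latent.shape
    values = np.zeros((n_cells, n_genes))
    values[:, :n_lat] = latent
    if n_genes > n_lat:
        values[:, n_lat:] = rng.normal(0.0, noise_sd, size=(n_cells, n_genes - n_lat))
    counts = np.rint(offset + scale * values)
    return np.maximum(counts, 0.0)


def generate_lineage(spec: LineageSpec) -> SyntheticDataset:
    """Generate a dataset whose clusters sit on the given lineage tree.

    Each tree edge is assigned its own orthonormal latent direction, so the
    centroid distance between two clusters is branch_length * sqrt(tree
    distance) — monotone in tree distance by construction.  Cells are
    centroid + isotropic Gaussian noise whose spread grows linearly with
    depth (density_gradient), and bridge cells are placed along the first
    half of parent->child segments, labeled with the parent.
    """
    rng = np.random.default_rng(spec.seed)
    n_lat = spec.n_informative_genes
    edges = spec.topology
    if len(edges) + 1 > n_lat:
        raise ValueError("need n_informative_genes > number of tree edges")
    # Each tree segment activates its own disjoint module of informative
    # genes (mimicking lineage-specific marker modules); the root gets a
    # module of its own so progenitors also have a distinctive signature.
    # Module activations accumulate along the path from the root and the
    # accumulated signature is then normalized onto a sphere of radius
    # sqrt(2) * branch_length: chordal centroid distance is strictly
    # increasing in tree distance (per row of the distance matrix), while
    # every cluster keeps the same signature magnitude, so cluster density
    # is governed by the within-cluster spread (progenitors tightest, hence
    # densest) rather than by signature size.
    n_modules = len(edges) + 1
    module_genes = np.array_split(np.arange(n_lat), n_modules)
    unit_dirs = []
    for genes in module_genes:
        v = np.zeros(n_lat)
        v[genes] = 1.0 / np.sqrt(genes.size)
        unit_dirs.append(v)
    depth = _tree_depths(spec)
    max_depth = max(depth.values()) or 1
    radius = spec.branch_length * np.sqrt(2.0)
    accum: dict[str, np.ndarray] = {spec.root: unit_dirs[len(edges)].copy()}
    pending = list(edges)
    directions = {edge: unit_dirs[e] for e, edge in enumerate(edges)}
    while pending:
        remaining = []
        for edge in pending:
            p, c = edge
            if p in accum:
                accum[c] = accum[p] + directions[edge]
            else:
                remaining.append(edge)
        pending = remaining
    centroids = {
        node: radius * vec / np.linalg.norm(vec) for node, vec in accum.items()
    }

    out_edges: dict[str, list[tuple[str, str]]] = {}
    for p, c in edges:
        out_edges.setdefault(p, []).append((p, c))

    cell_ids: list[str] = []
    labels: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for cluster in spec.clusters:
        sd = spec.within_cluster_sd * (
            1.0 + (spec.density_gradient - 1.0) * depth[cluster] / max_depth
        )
        n_bridge = (
            int(round(spec.bridge_fraction * spec.n_per_cluster))
            if out_edges.get(cluster)
            else 0
        )
        n_core = spec.n_per_cluster - n_bridge
        core = centroids[cluster] + rng.normal(0.0, sd, size=(n_core, n_lat))
        cluster_rows = [core]
        if n_bridge:
            targets = out_edges[cluster]
            picks = rng.integers(0, len(targets), size=n_bridge)
            t = rng.uniform(0.05, 0.5, size=n_bridge)
            bridge = np.empty((n_bridge, n_lat))
            for b in range(n_bridge):
                p, c = targets[picks[b]]
                seg = centroids[c] - centroids[p]
                bridge[b] = centroids[p] + t[b] * seg + rng.normal(
                    0.0, sd * 0.5, size=n_lat
                )
            cluster_rows.append(bridge)
        block = np.vstack(cluster_rows)
        for i in range(block.shape[0]):
            cid = f"{cluster}_{i:03d}"
            cell_ids.append(cid)
            labels[cid] = cluster
        rows.append(block)
    latent = np.vstack(rows)
    counts = _latent_to_counts(latent, spec.n_genes, rng,
                               noise_sd=spec.noise_gene_sd)
    matrix = ExpressionMatrix(
        values=counts.T,
        gene_ids=tuple(f"gene_{g:04d}" for g in range(spec.n_genes)),
        cell_ids=tuple(cell_ids),
        normalized=False,
    )
    adjacency = frozenset(frozenset(e) for e in edges)
    return SyntheticDataset(
        matrix=matrix,
        classes=ClassAssignment(labels),
        truth_adjacency=adjacency,
        spec=spec,
        centroids=centroids,
    )


def generate_unordered_triplet(
    n_per_cluster: int = 60,
    overlap: float = 0.5,
    n_genes: int = 200,
    seed: int = 0,
) -> SyntheticDataset:
    """Three mutually overlapping clusters with no ordering.

    Centroids form an equilateral triangle (side 2) in two latent
    dimensions; ``overlap`` is the ratio of within-cluster spread to the
    side length, so overlap -> 0 gives three separable blobs and larger
    values mix all three pairs symmetrically.
    """
    if overlap <= 0:
        raise ValueError("overlap must be > 0")
    rng = np.random.default_rng(seed)
    side = 2.0
    centroids = {
        "A": np.array([0.0, 0.0]),
        "B": np.array([side, 0.0]),
        "C": np.array([side / 2.0, side * np.sqrt(3.0) / 2.0]),
    }
    center = np.mean(list(centroids.values()), axis=0)
    centroids = {k: v - center for k, v in centroids.items()}
    sd = overlap * side
    cell_ids: list[str] = []
    labels: dict[str, str] = {}
    rows = []
    for cluster, mu in centroids.items():
        block = mu + rng.normal(0.0, sd, size=(n_per_cluster, 2))
        rows.append(block)
        for i in range(n_per_cluster):
            cid = f"{cluster}_{i:03d}"
            cell_ids.append(cid)
            labels[cid] = cluster
    latent = np.vstack(rows)
    counts = _latent_to_counts(latent, n_genes, rng)
    matrix = ExpressionMatrix(
        values=counts.T,
        gene_ids=tuple(f"gene_{g:04d}" for g in range(n_genes)),
        cell_ids=tuple(cell_ids),
        normalized=False,
    )
    return SyntheticDataset(
        matrix=matrix,
        classes=ClassAssignment(labels),
        truth_adjacency=frozenset(),
        spec=None,
        centroids=centroids,
    )


def informative_signal_dataset(
    n_cells_per_class: int = 50,
    n_genes: int = 200,
    n_informative: int = 10,
    n_classes: int = 2,
    effect: float = 2.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ClassAssignment, tuple[int, ...]]:
    """Classification fixture where only the first ``n_informative`` genes
    separate the classes; used to test feature selection recovers them."""
    rng = np.random.default_rng(seed)
    class_names = [chr(ord("A") + i) for i in range(n_classes)]
    rows = []
    cell_ids: list[str] = []
    labels: dict[str, str] = {}
    for ci, name in enumerate(class_names):
        signal = np.zeros(n_genes)
        signal[:n_informative] = effect * rng.choice(
            [-1.0, 1.0], size=n_informative
        ) * (ci + 1) / n_classes
        block = signal + rng.normal(0.0, 0.5, size=(n_cells_per_class, n_genes))
        rows.append(block)
        for i in range(n_cells_per_class):
            cid = f"{name}_{i:03d}"
            cell_ids.append(cid)
            labels[cid] = name
    values = np.rint(10.0 * np.exp(np.clip(np.vstack(rows), -6, 6)))
    matrix = ExpressionMatrix(
        values=values.T,
        gene_ids=tuple(f"gene_{g:04d}" for g in range(n_genes)),
        cell_ids=tuple(cell_ids),
        normalized=False,
    )
    return matrix, ClassAssignment(labels), tuple(range(n_informative))
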