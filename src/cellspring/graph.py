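"""Instance-graph construction.

Two edge types encode competing layout priors:

* **knn edges** connect each cell to its k nearest neighbors *of the same
  class*, pulling classes into compact groups.
* **shift edges** connect each cell to its k' nearest neighbors that are both
  *denser* and *of a different class*, restricted to the cell's h nearest
  neighbors (the knn horizon).  They implement quick-shift style mode
  seeking: differentiation trajectories are expected to ascend the density
  gradient from mature cells toward progenitors.

Density is the mean cosine similarity of a cell to all cells (self included),
which is robust to outliers because the cosine is normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core_io import (
    ClassAssignment,
    Edge,
    InstanceGraph,
    ProfileSpace,
    ValidationError,
)


@dataclass(frozen=True)
class GraphParams:
    """Parameters of the instance graph.

    k: same-class nearest neighbors per cell.
    k_shift: denser different-class neighbors per cell (the paper-style k').
    horizon: only a cell's ``horizon`` nearest neighbors are eligible shift
        targets; defaults to 10 * k_shift when unset.
    confidence: C >= 0, contracts knn desired lengths to d / (1 + C).
    """

    k: int = 3
    k_shift: int = 1
    horizon: int | None = None
    confidence: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k_shift < 0:
            raise ValueError("k_shift must be >= 0")
        if self.confidence < 0:
            raise ValueError("confidence must be >= 0")
        if self.horizon is not None and self.horizon < self.k_shift:
            raise ValueError("horizon must be >= k_shift")

    @property
    def effective_horizon(self) -> int:
        return self.horizon if self.horizon is not None else max(1, 10 * self.k_shift)


def pairwise_distance(space: ProfileSpace) -> np.ndarray:
    """Euclidean distance between every pair of profile vectors."""
    return squareform(pdist(space.vectors, metric="euclidean"))


def compute_density(space: ProfileSpace) -> np.ndarray:
    """Density D(p_i): mean cosine similarity of cell i to all cells."""
    norms = np.linalg.norm(space.vectors, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        bad = [space.cell_ids[i] for i in zero[:10]]
        raise ValidationError(f"zero-norm profile vectors for cells: {bad}")
    unit = space.vectors / norms[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    return cos.mean(axis=1)


def _neighbor_order(dist_row: np.ndarray, self_idx: int) -> np.ndarray:
    """Indices of all other cells sorted by distance, ties by lower index."""
    n = dist_row.shape[0]
    others = np.delete(np.arange(n), self_idx)
    order = np.lexsort((others, dist_row[others]))
    return others[order]


def knn_edges(dist: np.ndarray, classes: ClassAssignment, k: int,
              cell_ids: tuple[str, ...] | None = None,
              labels: list[str] | None = None) -> list[Edge]:
    """Connect each cell to its k nearest same-class neighbors.

    ``labels`` may be passed directly (positional, aligned with ``dist``);
    otherwise they are looked up from ``classes`` via ``cell_ids``.
    Edges are deduplicated as unordered pairs; desired length is the
    profile-space distance.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if labels is None:
        if cell_ids is None:
            raise ValueError("need labels or cell_ids")
        labels = classes.labels_for(cell_ids)
    labels_arr = np.asarray(labels)
    n = dist.shape[0]
    pairs: dict[tuple[int, int], float] = {}
    for i in range(n):
        order = _neighbor_order(dist[i], i)
        same = order[labels_arr[order] == labels_arr[i]]
        for j in same[:k]:
            key = (min(i, int(j)), max(i, int(j)))
            pairs.setdefault(key, float(dist[i, j]))
    return [Edge(a, b, "knn", d) for (a, b), d in sorted(pairs.items())]


def kshift_edges(
    dist: np.ndarray,
    density: np.ndarray,
    classes: ClassAssignment,
    k_shift: int,
    horizon: int,
    cell_ids: tuple[str, ...] | None = None,
    labels: list[str] | None = None,
) -> list[Edge]:
    """Connect each cell to its k' nearest denser different-class neighbors
    among its ``horizon`` nearest neighbors.

    Edges are directed from the sparser cell to the denser cell (stored as
    source -> target) and deduplicated as unordered pairs.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if labels is None:
        if cell_ids is None:
            raise ValueError("need labels or cell_ids")
        labels = classes.labels_for(cell_ids)
    labels_arr = np.asarray(labels)
    n = dist.shape[0]
    pairs: dict[tuple[int, int], Edge] = {}
    for i in range(n):
        order = _neighbor_order(dist[i], i)[:horizon]
        eligible = order[
            (density[order] > density[i]) & (labels_arr[order] != labels_arr[i])
        ]
        for j in eligible[:k_shift]:
            j = int(j)
            key = (min(i, j), max(i, j))
            pairs.setdefault(key, Edge(i, j, "shift", float(dist[i, j])))
    return [pairs[k] for k in sorted(pairs)]


def build_instance_graph(
    space: ProfileSpace, classes: ClassAssignment, params: GraphParams
) -> InstanceGraph:
    """Full graph stage: distances, densities, both edge types, confidence."""
    labels = classes.labels_for(space.cell_ids)
    dist = pairwise_distance(space)
    density = compute_density(space)
    edges = knn_edges(dist, classes, params.k, labels=labels)
    if params.k_shift > 0:
        edges = edges + kshift_edges(
            dist, density, classes, params.k_shift, params.effective_horizon,
            labels=labels,
        )
    graph = InstanceGraph(
        cell_ids=space.cell_ids,
        class_labels=tuple(labels),
        density=density,
        edges=tuple(edges),
    )
    return apply_confidence(graph, params.confidence)


def apply_confidence(graph: InstanceGraph, confidence: float) -> InstanceGraph:
    """Contract knn desired lengths to d / (1 + C); shift edges untouched.

    C = 0 is the identity; C = 1, 2, ... 9 magnify class separation two-,
    three-, ... ten-fold.
    """
    if confidence < 0:
        raise ValueError("confidence must be >= 0")
    if confidence == 0:
        return graph
    factor = 1.0 + confidence
    edges = tuple(
        Edge(e.source, e.target, e.kind, e.desired_length / factor)
        if e.kind == "knn"
        else e
        for e in graph.edges
    )
    return InstanceGraph(graph.cell_ids, graph.class_labels, graph.density, edges)
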