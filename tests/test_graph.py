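"""Density, distances, knn/shift edge construction and confidence
contraction, checked against brute-force oracles."""

import numpy as np
import pytest

from cellspring import (
    ClassAssignment,
    ProfileSpace,
    apply_confidence,
    build_instance_graph,
    compute_density,
    knn_edges,
    kshift_edges,
    pairwise_distance,
    validate_graph,
)
from cellspring.core_io import Edge, InstanceGraph
from cellspring.graph import GraphParams

from conftest import random_profile_space


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def oracle_distance(vectors: np.ndarray) -> np.ndarray:
    n = vectors.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.sqrt(((vectors[i] - vectors[j]) ** 2).sum())
    return out


def oracle_density(vectors: np.ndarray) -> np.ndarray:
    n = vectors.shape[0]
    out = np.zeros(n)
    for i in range(n):
        total = 0.0
        for j in range(n):
            num = float(vectors[i] @ vectors[j])
            den = np.sqrt(float(vectors[i] @ vectors[i]) * float(vectors[j] @ vectors[j]))
            total += num / den
        out[i] = total / n
    return out


def oracle_knn(dist, labels, k):
    pairs = set()
    n = dist.shape[0]
    for i in range(n):
        cands = sorted(
            (j for j in range(n) if j != i and labels[j] == labels[i]),
            key=lambda j: (dist[i, j], j),
        )
        for j in cands[:k]:
            pairs.add((min(i, j), max(i, j)))
    return pairs


def oracle_kshift(dist, density, labels, k_shift, horizon):
    pairs = set()
    n = dist.shape[0]
    for i in range(n):
        ordered = sorted((j for j in range(n) if j != i), key=lambda j: (dist[i, j], j))
        survivors = [
            j for j in ordered[:horizon]
            if density[j] > density[i] and labels[j] != labels[i]
        ]
        for j in survivors[:k_shift]:
            pairs.add((min(i, j), max(i, j)))
    return pairs


def _labels_for(n: int, n_classes: int, seed: int) -> list[str]:
    rng = np.random.default_rng(seed)
    return [chr(ord("A") + int(c)) for c in rng.integers(0, n_classes, n)]


class TestPairwiseDistance:
    def test_identical_rows_zero(self):
        space = ProfileSpace(np.ones((3, 4)), ("a", "b", "c"), is_correlation=False)
        assert pairwise_distance(space).max() == 0.0

    def test_orthonormal_pair(self):
        space = ProfileSpace(np.eye(2), ("a", "b"))
        assert pairwise_distance(space)[0, 1] == pytest.approx(np.sqrt(2))

    def test_matches_loop_oracle(self):
        space = random_profile_space(6, seed=0)
        np.testing.assert_allclose(
            pairwise_distance(space), oracle_distance(space.vectors), rtol=1e-9
        )

    def test_metric_properties(self):
        space = random_profile_space(10, seed=1)
        d = pairwise_distance(space)
        np.testing.assert_allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        # triangle inequality
        for i in range(10):
            for j in range(10):
                for m in range(10):
                    assert d[i, j] <= d[i, m] + d[m, j] + 1e-9


class TestComputeDensity:
    def test_identical_rows_density_one(self):
        space = ProfileSpace(np.tile([1.0, 2.0, 3.0], (4, 1)), tuple("abcd"),
                             is_correlation=False)
        np.testing.assert_allclose(compute_density(space), 1.0)

    def test_two_orthogonal_rows_half(self):
        space = ProfileSpace(np.eye(2), ("a", "b"))
        np.testing.assert_allclose(compute_density(space), [0.5, 0.5])

    def test_matches_cosine_loop_oracle(self):
        space = random_profile_space(7, seed=2)
        np.testing.assert_allclose(
            compute_density(space), oracle_density(space.vectors), rtol=1e-9
        )

    def test_invariant_to_positive_row_rescaling(self):
        rng = np.random.default_rng(3)
        V = rng.normal(size=(6, 5))
        s1 = ProfileSpace(V, tuple("abcdef"), is_correlation=False)
        s2 = ProfileSpace(V * rng.uniform(0.1, 5, size=(6, 1)), tuple("abcdef"),
                          is_correlation=False)
        np.testing.assert_allclose(compute_density(s1), compute_density(s2))


class TestKnnEdges:
    def test_line_of_four_cells_k1(self):
        # same-class cells on a line at 0, 1, 2, 3 -> chain edges
        x = np.array([[0.0], [1.0], [2.0], [3.0]])
        dist = oracle_distance(x)
        classes = ClassAssignment({f"c{i}": "A" for i in range(4)})
        edges = knn_edges(dist, classes, k=1, cell_ids=tuple(f"c{i}" for i in range(4)))
        assert {(e.source, e.target) for e in edges} == {(0, 1), (1, 2), (2, 3)}

    def test_k_at_least_class_size_gives_complete_subgraphs(self):
        space = random_profile_space(8, seed=4)
        dist = pairwise_distance(space)
        labels = ["A"] * 4 + ["B"] * 4
        edges = knn_edges(dist, None, k=10, labels=labels)
        got = {(e.source, e.target) for e in edges}
        expected = {(i, j) for i in range(8) for j in range(i + 1, 8)
                    if labels[i] == labels[j]}
        assert got == expected

    def test_singleton_classes_no_edges(self):
        space = random_profile_space(2, seed=5)
        dist = pairwise_distance(space)
        assert knn_edges(dist, None, k=1, labels=["A", "B"]) == []

    def test_desired_length_is_distance(self):
        space = random_profile_space(6, seed=6)
        dist = pairwise_distance(space)
        for e in knn_edges(dist, None, k=2, labels=_labels_for(6, 2, 0)):
            assert e.desired_length == pytest.approx(dist[e.source, e.target])


class TestKshiftEdges:
    def test_densest_cell_emits_no_edges(self):
        space = random_profile_space(10, seed=7)
        dist = pairwise_distance(space)
        density = compute_density(space)
        labels = _labels_for(10, 3, 1)
        top = int(np.argmax(density))
        edges = kshift_edges(dist, density, None, k_shift=3, horizon=9, labels=labels)
        assert all(e.source != top for e in edges)

    def test_denser_class_receives_all_edges(self):
        # class A directionally tight (dense), class B spread: cosine density
        # cares about angular spread, so A sits on a tight cone around a
        # non-zero centroid while B scatters widely around another
        rng = np.random.default_rng(2)
        V = np.vstack([
            np.array([5.0, 0.0, 0.0]) + rng.normal(0, 0.05, size=(5, 3)),
            np.array([4.0, 3.0, 0.0]) + rng.normal(0, 1.8, size=(5, 3)),
        ])
        space = ProfileSpace(V, tuple(f"c{i}" for i in range(10)),
                             is_correlation=False)
        dist = pairwise_distance(space)
        density = compute_density(space)
        labels = ["A"] * 5 + ["B"] * 5
        assert density[:5].min() > density[5:].max()
        edges = kshift_edges(dist, density, None, k_shift=2, horizon=9, labels=labels)
        assert edges, "fixture should produce shift edges"
        for e in edges:
            assert labels[e.source] == "B" and labels[e.target] == "A"
            assert density[e.target] > density[e.source]

    def test_horizon_one_same_class_neighbor_blocks(self):
        # three collinear cells: 0-1 same class adjacent, 2 far different class
        V = np.array([[0.0], [0.1], [5.0]])
        space = ProfileSpace(V, ("a", "b", "c"), is_correlation=False)
        dist = pairwise_distance(space)
        density = np.array([0.5, 0.9, 0.99])
        edges = kshift_edges(dist, density, None, k_shift=1, horizon=1,
                             labels=["A", "A", "B"])
        assert all(e.source != 0 for e in edges)

    @pytest.mark.parametrize("k_shift", [1, 2, 3])
    @pytest.mark.parametrize("horizon", [3, 10, 25])
    def test_matches_filter_and_sort_oracle(self, k_shift, horizon):
        for seed in range(10):
            space = random_profile_space(30, seed=100 + seed)
            dist = pairwise_distance(space)
            density = compute_density(space)
            labels = _labels_for(30, 3, seed)
            edges = kshift_edges(dist, density, None, k_shift, horizon, labels=labels)
            got = {(min(e.source, e.target), max(e.source, e.target)) for e in edges}
            assert got == oracle_kshift(dist, density, labels, k_shift, horizon)

    def test_knn_matches_oracle_on_grid(self):
        for seed in range(10):
            space = random_profile_space(30, seed=200 + seed)
            dist = pairwise_distance(space)
            labels = _labels_for(30, 3, seed + 50)
            for k in (1, 3, 7):
                edges = knn_edges(dist, None, k=k, labels=labels)
                got = {(e.source, e.target) for e in edges}
                assert got == oracle_knn(dist, labels, k)


class TestApplyConfidence:
    def _graph(self):
        return InstanceGraph(
            ("a", "b", "c", "d"),
            ("A", "A", "B", "B"),
            np.array([0.9, 0.8, 0.5, 0.4]),
            (Edge(0, 1, "knn", 2.0), Edge(2, 3, "knn", 1.0),
             Edge(2, 0, "shift", 2.0)),
        )

    def test_unit_confidence_halves_knn_lengths(self):
        out = apply_confidence(self._graph(), 1.0)
        knn = {(e.source, e.target): e.desired_length for e in out.edges_of_kind("knn")}
        assert knn == {(0, 1): 1.0, (2, 3): 0.5}

    def test_zero_confidence_is_identity(self):
        g = self._graph()
        assert apply_confidence(g, 0.0) is g

    def test_shift_edges_untouched(self):
        out = apply_confidence(self._graph(), 5.0)
        (shift,) = out.edges_of_kind("shift")
        assert shift.desired_length == 2.0

    @pytest.mark.parametrize("c", range(10))
    def test_contraction_factor_exact(self, c):
        out = apply_confidence(self._graph(), float(c))
        for e in out.edges_of_kind("knn"):
            orig = 2.0 if (e.source, e.target) == (0, 1) else 1.0
            assert e.desired_length * (1 + c) == pytest.approx(orig, rel=1e-12)

    def test_negative_confidence_rejected(self):
        with pytest.raises(ValueError):
            apply_confidence(self._graph(), -0.5)

    def test_topology_unchanged_lengths_strictly_decrease(self):
        g = self._graph()
        prev = {(e.source, e.target): e.desired_length for e in g.edges_of_kind("knn")}
        for c in (1.0, 2.0, 4.0):
            out = apply_confidence(g, c)
            assert [(e.source, e.target, e.kind) for e in out.edges] == [
                (e.source, e.target, e.kind) for e in g.edges
            ]
            cur = {(e.source, e.target): e.desired_length
                   for e in out.edges_of_kind("knn")}
            assert all(cur[k] < prev[k] for k in cur)
            prev = cur


class TestBuildInstanceGraph:
    def test_emitted_graph_satisfies_all_invariants(self):
        for seed in range(5):
            space = random_profile_space(25, seed=300 + seed)
            labels = _labels_for(25, 3, seed)
            classes = ClassAssignment(dict(zip(space.cell_ids, labels)))
            g = build_instance_graph(
                space, classes, GraphParams(k=3, k_shift=2, horizon=10,
                                            confidence=1.0)
            )
            validate_graph(g)

    def test_permutation_invariance_of_edge_sets(self):
        """Reordering the input cells never changes which cell pairs are
        connected (edges compared by cell id)."""
        space = random_profile_space(20, seed=400)
        labels = _labels_for(20, 3, 9)
        classes = ClassAssignment(dict(zip(space.cell_ids, labels)))
        params = GraphParams(k=2, k_shift=1, horizon=8)
        g1 = build_instance_graph(space, classes, params)
        rng = np.random.default_rng(1)
        perm = rng.permutation(20)
        space2 = ProfileSpace(
            space.vectors[np.ix_(perm, perm)],
            tuple(space.cell_ids[i] for i in perm),
        )
        g2 = build_instance_graph(space2, classes, params)

        def id_edges(g):
            return {
                (frozenset((g.cell_ids[e.source], g.cell_ids[e.target])), e.kind)
                for e in g.edges
            }

        assert id_edges(g1) == id_edges(g2)
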