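"""Force-directed layout of the instance graph (Kamada-Kawai spring model).

Every pair of cells i, j is joined by a spring whose rest length d_ij is the
weighted shortest-path distance between them on the instance graph and whose
strength is k_ij = K / d_ij^2.  The layout minimizes the total energy

    E = sum_{i<j} 1/2 k_ij (|v_i - v_j| - d_ij)^2

by repeatedly moving the single particle with the largest gradient magnitude
Delta_m = |(dE/dx_m, dE/dy_m)| to its local stable point with a 2-D
Newton-Raphson iteration.  Each Newton step is accepted only if it lowers
that particle's energy contribution (backtracking line search otherwise), so
the energy trace over accepted moves is non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse
from scipy.sparse.csgraph import connected_components, shortest_path

from .core_io import InstanceGraph, LayoutResult

_EPS = 1e-12


@dataclass(frozen=True)
class SpringSystem:
    """Desired distances and spring strengths for the layout.

    ``d`` is the symmetric matrix of shortest-path desired distances
    (``inf`` between disconnected vertices); ``k`` holds the spring
    strengths K / d^2, with 0 where there is no path.
    """

    d: np.ndarray
    k: np.ndarray
    K: float = 1.0

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "k", np.asarray(self.k, dtype=float))
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("desired distance matrix must be square")

    @property
    def n(self) -> int:
        return self.d.shape[0]


def _graph_adjacency(graph: InstanceGraph) -> scipy.sparse.csr_matrix:
    n = graph.n_cells
    rows, cols, vals = [], [], []
    for e in graph.edges:
        rows += [e.source, e.target]
        cols += [e.target, e.source]
        vals += [e.desired_length, e.desired_length]
    return scipy.sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def shortest_path_distances(graph: InstanceGraph, K: float = 1.0) -> SpringSystem:
    """All-pairs weighted shortest paths (Dijkstra) over the instance graph,
    using each edge's desired length as its weight."""
    if graph.n_cells < 1:
        raise ValueError("empty graph")
    adj = _graph_adjacency(graph)
    d = shortest_path(adj, method="D", directed=False)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(np.isfinite(d) & (d > 0), K / (d * d), 0.0)
    np.fill_diagonal(k, 0.0)
    return SpringSystem(d=d, k=k, K=K)


def kk_energy(positions: np.ndarray, system: SpringSystem) -> float:
    """Exact spring energy of a configuration (pairs without a path excluded)."""
    pos = np.asarray(positions, dtype=float)
    diff = pos[:, None, :] - pos[None, :, :]
    r = np.sqrt((diff**2).sum(-1))
    mask = system.k > 0
    resid = np.where(mask, r - np.where(mask, system.d, 0.0), 0.0)
    return float(0.5 * (system.k * resid**2).sum() / 2.0)  # /2: each pair twice


def _polygon_positions(n: int, radius: float) -> np.ndarray:
    theta = 2.0 * np.pi * np.arange(n) / n
    return radius * np.column_stack([np.cos(theta), np.sin(theta)])


def _particle_energy(pos_m: np.ndarray, P: np.ndarray, m: int, d: np.ndarray,
                     k: np.ndarray) -> float:
    """Energy of all springs attached to particle m with m placed at pos_m."""
    diff = pos_m - P
    r = np.sqrt((diff**2).sum(-1))
    resid = np.where(k > 0, r - np.where(k > 0, d, 0.0), 0.0)
    resid[m] = 0.0
    return float(0.5 * (k * resid**2).sum())


def _particle_gradient(P: np.ndarray, m: int, d_row: np.ndarray,
                       k_row: np.ndarray) -> np.ndarray:
    diff = P[m] - P
    r = np.sqrt((diff**2).sum(-1))
    r = np.maximum(r, _EPS)
    coef = k_row * (1.0 - np.where(k_row > 0, d_row, 0.0) / r)
    coef[m] = 0.0
    return (coef[:, None] * diff).sum(axis=0)


def _full_gradient(P: np.ndarray, system: SpringSystem) -> np.ndarray:
    diff = P[:, None, :] - P[None, :, :]
    r = np.sqrt((diff**2).sum(-1))
    r = np.maximum(r, _EPS)
    coef = system.k * (1.0 - np.where(system.k > 0, system.d, 0.0) / r)
    np.fill_diagonal(coef, 0.0)
    return (coef[:, :, None] * diff).sum(axis=1)


def _particle_hessian(P: np.ndarray, m: int, d_row: np.ndarray,
                      k_row: np.ndarray) -> tuple[float, float, float]:
    """(d2E/dx2, d2E/dxdy, d2E/dy2) for particle m."""
    diff = P[m] - P
    r = np.sqrt((diff**2).sum(-1))
    r = np.maximum(r, _EPS)
    d = np.where(k_row > 0, d_row, 0.0)
    k = k_row.copy()
    k[m] = 0.0
    r3 = r**3
    dx, dy = diff[:, 0], diff[:, 1]
    exx = float((k * (1.0 - d * dy**2 / r3)).sum())
    eyy = float((k * (1.0 - d * dx**2 / r3)).sum())
    exy = float((k * d * dx * dy / r3).sum())
    return exx, exy, eyy


def _descend_particle(P: np.ndarray, m: int, d_row: np.ndarray, k_row: np.ndarray,
                      tol: float, max_inner: int = 50) -> bool:
    """Move particle m toward its stable point; returns True if it moved.

    Newton steps with backtracking; a (near-)singular Newton system falls
    back to a damped gradient step.  Only energy-decreasing positions are
    accepted.
    """
    moved = False
    for _ in range(max_inner):
        g = _particle_gradient(P, m, d_row, k_row)
        gnorm = float(np.linalg.norm(g))
        if gnorm < tol:
            break
        exx, exy, eyy = _particle_hessian(P, m, d_row, k_row)
        det = exx * eyy - exy * exy
        if abs(det) > 1e-12:
            step = np.array(
                [(-g[0] * eyy + g[1] * exy) / det, (-g[1] * exx + g[0] * exy) / det]
            )
        else:
            scale = abs(exx) + abs(eyy)
            step = -g / (scale if scale > _EPS else 1.0)
        e0 = _particle_energy(P[m], P, m, d_row, k_row)
        accepted = False
        for direction in (step, -g / max(gnorm, _EPS)):
            alpha = 1.0
            for _ in range(40):
                cand = P[m] + alpha * direction
                if _particle_energy(cand, P, m, d_row, k_row) < e0 - 1e-15:
                    P[m] = cand
                    accepted = True
                    moved = True
                    break
                alpha *= 0.5
            if accepted:
                break
        if not accepted:
            break
    return moved


def kk_layout(
    system: SpringSystem,
    tol: float = 1e-4,
    max_iter: int | None = None,
    seed: int = 0,
) -> LayoutResult:
    """Minimize the spring energy one particle at a time.

    Particles start on a regular n-polygon (radius half the largest desired
    distance, vertex order = input order); at each outer iteration the
    particle with the largest gradient magnitude is relaxed by the inner
    Newton iteration.  Terminates when max_m Delta_m < tol or after
    ``max_iter`` particle selections (default 100 n).  Deterministic.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    n = system.n
    if n == 1:
        return LayoutResult(np.zeros((1, 2)), 0.0, 0, True, (0.0,))
    if max_iter is None:
        max_iter = 100 * n
    finite = system.d[np.isfinite(system.d) & (system.k > 0)]
    radius = float(finite.max()) / 2.0 if finite.size else 1.0
    P = _polygon_positions(n, max(radius, _EPS))
    energy0 = kk_energy(P, system)
    G = _full_gradient(P, system)
    trace = [energy0]
    iterations = 0
    converged = False
    for _ in range(max_iter):
        delta = np.linalg.norm(G, axis=1)
        m = int(delta.argmax())
        if delta[m] < tol:
            converged = True
            break
        iterations += 1
        old = P[m].copy()
        moved = _descend_particle(P, m, system.d[m], system.k[m], tol)
        if not moved:
            # argmax particle cannot improve: treat as numerically stuck
            break
        # incremental gradient update: only pair terms involving m changed
        diff_new = P - P[m]
        diff_old = P - old
        r_new = np.maximum(np.sqrt((diff_new**2).sum(-1)), _EPS)
        r_old = np.maximum(np.sqrt((diff_old**2).sum(-1)), _EPS)
        d_col = np.where(system.k[:, m] > 0, system.d[:, m], 0.0)
        k_col = system.k[:, m].copy()
        k_col[m] = 0.0
        coef_new = k_col * (1.0 - d_col / r_new)
        coef_old = k_col * (1.0 - d_col / r_old)
        G += coef_new[:, None] * diff_new - coef_old[:, None] * diff_old
        G[m] = _particle_gradient(P, m, system.d[m], system.k[m])
        trace.append(trace[-1] + _particle_energy(P[m], P, m, system.d[m], system.k[m])
                     - _particle_energy(old, P, m, system.d[m], system.k[m]))
    final_energy = kk_energy(P, system)
    if final_energy > energy0 + 1e-9 * max(1.0, energy0):
        raise AssertionError("layout energy exceeded the initial configuration")
    return LayoutResult(
        positions=P,
        final_energy=final_energy,
        iterations=iterations,
        converged=converged,
        energy_trace=tuple(trace),
    )


def _subsystem(system: SpringSystem, idx: np.ndarray) -> SpringSystem:
    return SpringSystem(system.d[np.ix_(idx, idx)], system.k[np.ix_(idx, idx)],
                        system.K)


def layout_components(
    graph: InstanceGraph,
    K: float = 1.0,
    tol: float = 1e-4,
    max_iter: int | None = None,
    seed: int = 0,
) -> LayoutResult:
    """Lay out each connected component independently, then pack the
    components on a grid with margins proportional to their bounding boxes."""
    n = graph.n_cells
    if n == 0:
        return LayoutResult(np.zeros((0, 2)), 0.0, 0, True, ())
    adj = _graph_adjacency(graph)
    n_comp, labels = connected_components(adj, directed=False)
    system = shortest_path_distances(graph, K=K)
    positions = np.zeros((n, 2))
    total_energy = 0.0
    total_iter = 0
    converged = True
    boxes: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []  # idx, pos, size
    order = sorted(range(n_comp), key=lambda c: -(labels == c).sum())
    for c in order:
        idx = np.flatnonzero(labels == c)
        if idx.size == 1:
            boxes.append((idx, np.zeros((1, 2)), np.zeros(2)))
            continue
        res = kk_layout(_subsystem(system, idx), tol=tol, max_iter=max_iter, seed=seed)
        pos = res.positions - res.positions.min(axis=0)
        boxes.append((idx, pos, pos.max(axis=0)))
        total_energy += res.final_energy
        total_iter += res.iterations
        converged = converged and res.converged
    if n_comp == 1:
        idx, pos, _ = boxes[0]
        positions[idx] = pos
        return LayoutResult(positions, total_energy, total_iter, converged)
    cell = max((b[2].max() for b in boxes), default=1.0)
    cell = cell * 1.2 + 1.0
    ncols = int(np.ceil(np.sqrt(n_comp)))
    for rank, (idx, pos, _) in enumerate(boxes):
        origin = np.array([(rank % ncols) * cell, (rank // ncols) * cell])
        positions[idx] = pos + origin
    return LayoutResult(positions, total_energy, total_iter, converged)
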