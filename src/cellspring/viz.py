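"""Rendering: layout scatter with class hulls and shift-edge overlay, and
ternary probability plots."""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")  # headless backend; must precede pyplot import
import matplotlib.pyplot as plt
import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .core_io import InstanceGraph, LayoutResult
from .ternary import ConfusionAnalysis, TernaryResult, ternary_coordinates


def class_color(label: str) -> tuple[float, float, float]:
    """Stable class color from a hash of the label, so figures are
    comparable across runs and input orderings."""
    digest = hashlib.sha256(label.encode()).digest()
    idx = digest[0] % 20
    return plt.get_cmap("tab20")(idx)[:3]


def class_convex_hulls(
    layout: LayoutResult, classes: Sequence[str]
) -> dict[str, np.ndarray]:
    """Per-class 2-D convex hull vertices (in hull order).

    Classes with <= 2 cells, or with collinear cells, yield degenerate
    polygons (the point or segment endpoints).
    """
    pos = layout.positions
    if len(classes) != pos.shape[0]:
        raise ValueError("classes misaligned with layout")
    hulls: dict[str, np.ndarray] = {}
    for label in dict.fromkeys(classes):
        pts = pos[np.asarray(classes) == label]
        if pts.shape[0] <= 2:
            hulls[label] = pts.copy()
            continue
        try:
            hull = ConvexHull(pts)
            hulls[label] = pts[hull.vertices]
        except QhullError:  # collinear points: segment between extremes
            span = pts - pts.mean(axis=0)
            axis = span[np.abs(span).sum(axis=1).argmax()]
            proj = span @ axis
            hulls[label] = pts[[int(proj.argmin()), int(proj.argmax())]]
    return hulls


def render_layout(
    layout: LayoutResult,
    graph: InstanceGraph,
    classes: Sequence[str],
    path: str | Path,
    show_hulls: bool = True,
    show_shift_edges: bool = True,
    show_knn_edges: bool = False,
    dpi: int = 150,
    title: str | None = None,
) -> Path:
    """Scatter of the layout colored by class, with optional hull outlines
    and edge overlays.  Writes PNG or SVG by file extension."""
    pos = layout.positions
    fig, ax = plt.subplots(figsize=(8, 8))
    if show_knn_edges:
        for e in graph.edges_of_kind("knn"):
            ax.plot(*pos[[e.source, e.target]].T, color="0.85", lw=0.5, zorder=1)
    if show_shift_edges:
        for e in graph.edges_of_kind("shift"):
            ax.plot(*pos[[e.source, e.target]].T, color="0.3", lw=0.8, zorder=2)
    labels = list(classes)
    for label in dict.fromkeys(labels):
        mask = np.asarray(labels) == label
        color = class_color(label)
        ax.scatter(*pos[mask].T, s=18, color=color, label=label, zorder=3)
    if show_hulls:
        for label, verts in class_convex_hulls(layout, labels).items():
            if verts.shape[0] >= 3:
                closed = np.vstack([verts, verts[:1]])
                ax.plot(*closed.T, color=class_color(label), lw=1.2, zorder=4)
    ax.set_aspect("equal")
    ax.legend(loc="best", fontsize=8)
    if title:
        ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    path = Path(path)
    _save(fig, path, dpi)
    plt.close(fig)
    return path


def _save(fig, path: Path, dpi: int) -> None:
    # fixed hashsalt + no creation date: identical inputs -> identical SVG bytes
    kwargs = {"metadata": {"Date": None}} if path.suffix == ".svg" else {}
    with plt.rc_context({"svg.hashsalt": "cellspring"}):
        fig.savefig(path, dpi=dpi, bbox_inches="tight", **kwargs)


def render_ternary(
    result: TernaryResult,
    analysis: ConfusionAnalysis | None,
    path: str | Path,
    dpi: int = 150,
) -> Path:
    """Ternary scatter of the probability triples inside the unit-side
    triangle, class labels at the vertices, confusion score annotated."""
    fig, ax = plt.subplots(figsize=(7, 6.5))
    corners = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0]])
    frame = np.vstack([corners, corners[:1]])
    ax.plot(*frame.T, color="black", lw=1.0)
    for corner, label, (ha, va, off) in zip(
        corners,
        result.triplet,
        [("right", "top", (-0.02, -0.02)), ("left", "top", (0.02, -0.02)),
         ("center", "bottom", (0.0, 0.02))],
    ):
        ax.text(corner[0] + off[0], corner[1] + off[1], label, ha=ha, va=va)
    xy = np.array([ternary_coordinates(t) for t in result.probabilities])
    for label in result.triplet:
        mask = np.asarray(result.true_labels) == label
        ax.scatter(*xy[mask].T, s=16, color=class_color(label), label=label)
    if analysis is not None:
        note = "degenerate" if analysis.degenerate else f"S = {analysis.score:.3f}"
        ax.text(0.02, 0.95, f"confusion score {note}", transform=ax.transAxes)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.legend(loc="upper right", fontsize=8)
    path = Path(path)
    _save(fig, path, dpi)
    plt.close(fig)
    return path
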