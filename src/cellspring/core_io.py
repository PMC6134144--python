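"""Domain types shared by all pipeline stages, plus readers and writers.

The pipeline operates on a genes x cells expression matrix with a per-cell
class assignment (a prior clustering).  Internally everything is indexed
positionally; cell and gene identifiers are opaque strings mapped to indices
once at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when parsed data violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x cells expression matrix.

    ``values[g, c]`` is the (raw or normalized) expression of gene ``g`` in
    cell ``c``.  Raw matrices hold non-negative integer counts (e.g. UMIs).
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    cell_ids: tuple[str, ...]
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        if values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"matrix shape {values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.cell_ids)} cells)"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")
        if not np.all(np.isfinite(values)):
            raise ValidationError("non-finite expression values")
        if np.any(values < 0):
            raise ValidationError("negative expression values")
        if not self.normalized and not np.allclose(values, np.round(values)):
            raise ValidationError("raw count matrix contains non-integer values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset_cells(self, indices: Sequence[int]) -> "ExpressionMatrix":
        idx = list(indices)
        return replace(
            self,
            values=self.values[:, idx],
            cell_ids=tuple(self.cell_ids[i] for i in idx),
        )

    def subset_genes(self, indices: Sequence[int]) -> "ExpressionMatrix":
        idx = list(indices)
        return replace(
            self,
            values=self.values[idx, :],
            gene_ids=tuple(self.gene_ids[i] for i in idx),
        )


@dataclass(frozen=True)
class ClassAssignment:
    """Mapping from cell id to class label (the user-supplied clustering)."""

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "labels", {str(k): str(v) for k, v in dict(self.labels).items()}
        )
        if not self.labels:
            raise ValidationError("no assignments")

    @property
    def classes(self) -> tuple[str, ...]:
        """Distinct class labels in first-appearance order."""
        seen: dict[str, None] = {}
        for lab in self.labels.values():
            seen.setdefault(lab, None)
        return tuple(seen)

    @property
    def class_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for lab in self.labels.values():
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes

    def labels_for(self, cell_ids: Sequence[str]) -> list[str]:
        missing = [c for c in cell_ids if c not in self.labels]
        if missing:
            raise ValidationError(
                f"{len(missing)} cell(s) missing from class assignment, "
                f"e.g. {missing[:5]}"
            )
        return [self.labels[c] for c in cell_ids]

    def subset(self, cell_ids: Iterable[str]) -> "ClassAssignment":
        return ClassAssignment({c: self.labels[c] for c in cell_ids})


@dataclass(frozen=True)
class ProfileSpace:
    """Per-cell feature vectors used for all distance computations.

    After the correlation transform each cell is described by its Pearson
    correlation to every cell, so ``vectors`` is n x n with unit diagonal and
    entries in [-1, 1].  When the transform is disabled the rows are plain
    (normalized) expression vectors and those invariants are not enforced.
    """

    vectors: np.ndarray
    cell_ids: tuple[str, ...]
    is_correlation: bool = True

    def __post_init__(self) -> None:
        vectors = np.asarray(self.vectors, dtype=float)
        object.__setattr__(self, "vectors", vectors)
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        if vectors.ndim != 2 or vectors.shape[0] != len(self.cell_ids):
            raise ValidationError("profile vectors misaligned with cell ids")
        if self.is_correlation:
            if vectors.shape[0] != vectors.shape[1]:
                raise ValidationError("correlation profile space must be square")
            if np.any(vectors < -1 - 1e-9) or np.any(vectors > 1 + 1e-9):
                raise ValidationError("correlation entries outside [-1, 1]")
            if not np.allclose(np.diag(vectors), 1.0, atol=1e-9):
                raise ValidationError("correlation diagonal must be 1")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


EdgeKind = Literal["knn", "shift"]


@dataclass(frozen=True)
class Edge:
    """A typed edge between two cells (positional indices).

    For shift edges ``source`` is the less dense endpoint and ``target`` the
    denser one; knn edges are undirected and stored with source < target.
    """

    source: int
    target: int
    kind: EdgeKind
    desired_length: float


@dataclass(frozen=True)
class InstanceGraph:
    """Cells as vertices with typed knn/shift edges carrying desired lengths."""

    cell_ids: tuple[str, ...]
    class_labels: tuple[str, ...]
    density: np.ndarray
    edges: tuple[Edge, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cell_ids", tuple(self.cell_ids))
        object.__setattr__(self, "class_labels", tuple(self.class_labels))
        object.__setattr__(self, "density", np.asarray(self.density, dtype=float))
        object.__setattr__(self, "edges", tuple(self.edges))

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def edges_of_kind(self, kind: EdgeKind) -> list[Edge]:
        return [e for e in self.edges if e.kind == kind]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, (cid, lab) in enumerate(zip(self.cell_ids, self.class_labels)):
            g.add_node(i, cell_id=cid, class_label=lab, density=float(self.density[i]))
        for e in self.edges:
            g.add_edge(
                e.source, e.target, kind=e.kind, desired_length=float(e.desired_length)
            )
        return g


def validate_graph(graph: InstanceGraph) -> None:
    """Check every InstanceGraph invariant; raise ValidationError on failure."""
    n = graph.n_cells
    if len(graph.class_labels) != n or graph.density.shape != (n,):
        raise ValidationError("graph vertex attributes misaligned")
    seen: set[tuple[int, int, str]] = set()
    for e in graph.edges:
        if not (0 <= e.source < n and 0 <= e.target < n):
            raise ValidationError(f"edge endpoint out of range: {e}")
        if e.source == e.target:
            raise ValidationError(f"self-loop: {e}")
        if e.desired_length <= 0:
            raise ValidationError(f"non-positive desired length: {e}")
        key = (min(e.source, e.target), max(e.source, e.target), e.kind)
        if key in seen:
            raise ValidationError(f"duplicate edge: {e}")
        seen.add(key)
        same_class = graph.class_labels[e.source] == graph.class_labels[e.target]
        if e.kind == "knn" and not same_class:
            raise ValidationError(f"knn edge across classes: {e}")
        if e.kind == "shift":
            if same_class:
                raise ValidationError(f"shift edge within a class: {e}")
            if not graph.density[e.target] > graph.density[e.source]:
                raise ValidationError(f"shift edge does not ascend density: {e}")


@dataclass(frozen=True)
class LayoutResult:
    """2-D coordinates per cell produced by the spring layout."""

    positions: np.ndarray
    final_energy: float
    iterations: int
    converged: bool = True
    energy_trace: tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValidationError("positions must be n x 2")
        if self.final_energy < -1e-12:
            raise ValidationError("negative layout energy")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_SEPARATORS = {"tsv": "\t", "csv": ","}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "csv", "mtx", "txt"):
        return "tsv" if suffix == "txt" else suffix
    raise ParseError(f"cannot infer format from {path.name}; pass format=")


def read_expression_matrix(
    path: str | Path,
    format: str | None = None,
    transpose: bool = False,
    normalized: bool = False,
) -> ExpressionMatrix:
    """Read a genes-in-rows x cells-in-columns matrix from TSV/CSV/MTX.

    For ``mtx``, gene and cell names are read from the sidecar files
    ``<stem>.rows.txt`` and ``<stem>.cols.txt``.  ``transpose=True`` flips
    the orientation after reading (for cells-in-rows dumps).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "mtx":
        rows_file = path.with_suffix(".rows.txt")
        cols_file = path.with_suffix(".cols.txt")
        for side in (rows_file, cols_file):
            if not side.exists():
                raise FileNotFoundError(f"missing MTX sidecar name file {side}")
        values = scipy.io.mmread(path)
        if scipy.sparse.issparse(values):
            values = values.toarray()
        gene_ids = rows_file.read_text().split()
        cell_ids = cols_file.read_text().split()
    else:
        if fmt not in _SEPARATORS:
            raise ParseError(f"unsupported format {fmt!r}")
        try:
            df = pd.read_csv(path, sep=_SEPARATORS[fmt], index_col=0)
        except Exception as exc:  # pandas raises a zoo of parse errors
            raise ParseError(f"cannot parse {path}: {exc}") from exc
        if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
            bad = [c for c, dt in df.dtypes.items() if not np.issubdtype(dt, np.number)]
            raise ParseError(f"non-numeric column(s) in {path}: {bad[:5]}")
        values = df.to_numpy(dtype=float)
        gene_ids = [str(i) for i in df.index]
        cell_ids = [str(c) for c in df.columns]
    if transpose:
        values = np.asarray(values).T
        gene_ids, cell_ids = cell_ids, gene_ids
    return ExpressionMatrix(
        values=np.asarray(values, dtype=float),
        gene_ids=tuple(gene_ids),
        cell_ids=tuple(cell_ids),
        normalized=normalized,
    )


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, format: str | None = None
) -> Path:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(matrix.values))
        path.with_suffix(".rows.txt").write_text("\n".join(matrix.gene_ids) + "\n")
        path.with_suffix(".cols.txt").write_text("\n".join(matrix.cell_ids) + "\n")
    else:
        df = pd.DataFrame(
            matrix.values, index=list(matrix.gene_ids), columns=list(matrix.cell_ids)
        )
        df.to_csv(path, sep=_SEPARATORS[fmt])
    return path


_CLASS_HEADERS = {"cell_id", "cell", "id", "cellid"}


def read_class_assignment(path: str | Path) -> ClassAssignment:
    """Read a two-column (cell_id, class_label) table; header row optional."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            rows.append((parts[0].strip(), parts[1].strip()))
    if rows and rows[0][0].lower() in _CLASS_HEADERS:
        rows = rows[1:]
    if not rows:
        raise ParseError(f"{path}: no assignments")
    labels: dict[str, str] = {}
    for cid, lab in rows:
        if cid in labels:
            raise ValidationError(f"duplicate cell id {cid!r} in {path}")
        labels[cid] = lab
    return ClassAssignment(labels)


def write_class_assignment(classes: ClassAssignment, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("cell_id\tclass\n")
        for cid, lab in classes.labels.items():
            fh.write(f"{cid}\t{lab}\n")
    return path


def write_graph(
    graph: InstanceGraph, path: str | Path, format: Literal["graphml", "tsv"] = "tsv"
) -> Path:
    """Serialize the instance graph with edge kind and desired length.

    The edge-list TSV has fixed columns source_id, target_id, kind,
    desired_length (6 significant digits); GraphML keeps full precision.
    """
    validate_graph(graph)
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph.to_networkx(), path)
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("source_id\ttarget_id\tkind\tdesired_length\n")
            for e in graph.edges:
                fh.write(
                    f"{graph.cell_ids[e.source]}\t{graph.cell_ids[e.target]}\t"
                    f"{e.kind}\t{e.desired_length:.6g}\n"
                )
    else:
        raise ValueError(f"unsupported graph format {format!r}")
    return path


def read_graph(
    path: str | Path,
    format: Literal["graphml", "tsv"] = "tsv",
    density: np.ndarray | None = None,
    class_labels: Sequence[str] | None = None,
    cell_ids: Sequence[str] | None = None,
) -> InstanceGraph:
    """Read a graph written by :func:`write_graph`.

    GraphML files are self-contained.  Edge-list TSV files carry no vertex
    attributes, so ``cell_ids``, ``class_labels`` and ``density`` must be
    supplied to rebuild a full InstanceGraph from them.
    """
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        order = sorted(g.nodes, key=int)
        cids = [g.nodes[v]["cell_id"] for v in order]
        labs = [g.nodes[v]["class_label"] for v in order]
        dens = np.array([float(g.nodes[v]["density"]) for v in order])
        index = {v: i for i, v in enumerate(order)}
        edges = []
        for u, v, data in g.edges(data=True):
            i, j = index[u], index[v]
            kind = data["kind"]
            length = float(data["desired_length"])
            if kind == "shift" and dens[i] > dens[j]:
                i, j = j, i
            elif kind == "knn" and i > j:
                i, j = j, i
            edges.append(Edge(i, j, kind, length))
        edges.sort(key=lambda e: (e.kind, e.source, e.target))
        return InstanceGraph(tuple(cids), tuple(labs), dens, tuple(edges))
    if format != "tsv":
        raise ValueError(f"unsupported graph format {format!r}")
    if cell_ids is None or class_labels is None or density is None:
        raise ValueError("edge-list TSV requires cell_ids, class_labels and density")
    index = {c: i for i, c in enumerate(cell_ids)}
    edges = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["source_id", "target_id", "kind", "desired_length"]:
            raise ParseError(f"{path}: unexpected edge-list header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            src, tgt, kind, length = parts
            if kind not in ("knn", "shift"):
                raise ParseError(f"{path}:{lineno}: unknown edge kind {kind!r}")
            edges.append(Edge(index[src], index[tgt], kind, float(length)))
    return InstanceGraph(
        tuple(cell_ids), tuple(class_labels), np.asarray(density, float), tuple(edges)
    )


def write_layout(
    layout: LayoutResult,
    cell_ids: Sequence[str],
    classes: Sequence[str],
    path: str | Path,
) -> Path:
    """Write a TSV with columns cell_id, class, x, y (one row per cell)."""
    n = layout.positions.shape[0]
    if len(cell_ids) != n or len(classes) != n:
        raise ValidationError(
            f"layout has {n} cells but got {len(cell_ids)} ids / {len(classes)} classes"
        )
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("cell_id\tclass\tx\ty\n")
        for cid, lab, (x, y) in zip(cell_ids, classes, layout.positions):
            fh.write(f"{cid}\t{lab}\t{x:.10g}\t{y:.10g}\n")
    return path


def read_layout(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "class": str})
    expected = ["cell_id", "class", "x", "y"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return df
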