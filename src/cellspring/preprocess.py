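"""Pre-processing: class filtering, UMI normalization, recursive feature
elimination, and the Pearson correlation transform.

The fixed stage order is filter -> normalize -> select -> transform.  The
correlation transform re-describes each cell by its Pearson correlation to
every cell, so downstream similarity depends only on the shape of the
expression pattern, not its magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import clone
from sklearn.linear_model import SGDClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .core_io import ClassAssignment, ExpressionMatrix, ProfileSpace, ValidationError


def filter_classes(
    matrix: ExpressionMatrix, classes: ClassAssignment, min_size: int
) -> tuple[ExpressionMatrix, ClassAssignment]:
    """Drop every class with fewer than ``min_size`` cells (and its cells).

    The relative order of surviving cells is preserved.  Raises if fewer
    than two classes survive.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    labels = classes.labels_for(matrix.cell_ids)
    sizes: dict[str, int] = {}
    for lab in labels:
        sizes[lab] = sizes.get(lab, 0) + 1
    keep_classes = {lab for lab, n in sizes.items() if n >= min_size}
    if len(keep_classes) < 2:
        raise ValidationError(
            f"insufficient classes: only {len(keep_classes)} class(es) have "
            f">= {min_size} cells"
        )
    keep_idx = [i for i, lab in enumerate(labels) if lab in keep_classes]
    sub = matrix.subset_cells(keep_idx)
    return sub, classes.subset(sub.cell_ids)


def normalize_umi(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Equalize library size: divide each cell by its total count, then
    rescale by the median of the original per-cell totals so values stay
    count-like."""
    if matrix.normalized:
        raise ValidationError("matrix is already normalized")
    totals = matrix.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = [matrix.cell_ids[i] for i in zero[:10]]
        raise ValidationError(f"cells with zero total counts: {bad}")
    scaled = matrix.values / totals * np.median(totals)
    return ExpressionMatrix(
        values=scaled,
        gene_ids=matrix.gene_ids,
        cell_ids=matrix.cell_ids,
        normalized=True,
    )


@dataclass(frozen=True)
class RfeResult:
    """Outcome of recursive feature elimination.

    ``cv_accuracy_trace`` records (n_features, CV accuracy) for every feature
    set evaluated, in elimination order; ``selected_gene_indices`` is the set
    attaining the best accuracy.
    """

    selected_gene_indices: tuple[int, ...]
    cv_accuracy_trace: tuple[tuple[int, float], ...]
    best_accuracy: float


def _make_estimator(seed: int) -> SGDClassifier:
    # Linear hinge-loss model with L2 regularization; multi-class is
    # one-vs-all by construction in SGDClassifier.
    return SGDClassifier(loss="hinge", penalty="l2", random_state=seed)


def rfe_select(
    matrix: ExpressionMatrix,
    classes: ClassAssignment,
    step: int = 20,
    folds: int = 5,
    seed: int = 0,
    patience: int = 1,
) -> RfeResult:
    """Recursive feature elimination with a linear SVM trained by SGD.

    At each round the model is refit on the surviving genes, per-gene
    importance is the L2 norm of its weights across the one-vs-all
    classifiers, the ``step`` least important genes are removed, and
    stratified ``folds``-fold CV accuracy is recorded.  Elimination stops
    once accuracy has failed to beat the best seen for ``patience + 1``
    consecutive rounds (or genes run out); the best-scoring feature set is
    returned.  Fully deterministic given ``seed``.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    labels = np.asarray(classes.labels_for(matrix.cell_ids))
    smallest = min(np.unique(labels, return_counts=True)[1])
    if folds > smallest:
        raise ValidationError(
            f"cv folds ({folds}) exceed smallest class size ({smallest})"
        )
    X_full = matrix.values.T  # cells x genes
    current = np.arange(matrix.n_genes)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    trace: list[tuple[int, float]] = []
    best_acc = -np.inf
    best_set = current.copy()
    rounds_since_best = 0
    while True:
        X = X_full[:, current]
        acc = float(
            cross_val_score(_make_estimator(seed), X, labels, cv=cv, n_jobs=None).mean()
        )
        trace.append((current.size, acc))
        if acc > best_acc:
            best_acc = acc
            best_set = current.copy()
            rounds_since_best = 0
        else:
            rounds_since_best += 1
            if rounds_since_best > patience:
                break
        if current.size <= 1:
            break
        model = clone(_make_estimator(seed)).fit(X, labels)
        coef = np.atleast_2d(model.coef_)
        importance = np.linalg.norm(coef, axis=0)
        n_remove = min(step, current.size - 1)
        # ties broken toward lower gene index for determinism
        order = np.lexsort((current, importance))
        drop = set(order[:n_remove].tolist())
        current = np.array([g for i, g in enumerate(current) if i not in drop])
    return RfeResult(
        selected_gene_indices=tuple(int(i) for i in np.sort(best_set)),
        cv_accuracy_trace=tuple(trace),
        best_accuracy=best_acc,
    )


def correlation_transform(matrix: ExpressionMatrix) -> ProfileSpace:
    """Map each cell to its vector of Pearson correlations with all cells.

    Entry (i, j) is rho(z_i, z_j) over the (selected) genes; the output is a
    symmetric n x n matrix with unit diagonal.
    """
    X = matrix.values.T  # cells x genes
    sd = X.std(axis=1)
    zero_var = np.flatnonzero(sd == 0)
    if zero_var.size:
        bad = [matrix.cell_ids[i] for i in zero_var[:10]]
        raise ValidationError(f"cells with zero expression variance: {bad}")
    corr = np.corrcoef(X)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return ProfileSpace(vectors=corr, cell_ids=matrix.cell_ids, is_correlation=True)
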