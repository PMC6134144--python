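"""Transition analysis for a triplet of classes.

To test whether one class is a transitional state between two others, each
cell of the three classes gets an out-of-fold class-probability triple from
one-vs-rest logistic regression, the triples are plotted on the probability
simplex, and a scalar confusion score summarizes the structure: class-
averaged probabilities form a 3x3 confusion matrix D, its symmetrized
off-diagonals form the pairwise error vector E = (E_12, E_13, E_23), and

    S = min(E) / sum of the other two components.

A small S means one class pair is cleanly separated while the other two
pairs are confused — the signature of a transition through the shared class.
S = 0.5 is maximal confusion (all pairs equally mixed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .core_io import ClassAssignment, ProfileSpace, ValidationError

SQRT3 = float(np.sqrt(3.0))


class ProbabilityTriple(NamedTuple):
    """Estimated membership probabilities in the three classes (sum to 1)."""

    a: float
    b: float
    c: float


@dataclass(frozen=True)
class TernaryResult:
    """Per-cell probability triples for a class triplet."""

    triplet: tuple[str, str, str]
    cell_ids: tuple[str, ...]
    true_labels: tuple[str, ...]
    probabilities: np.ndarray  # n x 3, rows sum to 1, columns follow triplet

    def triples(self) -> list[ProbabilityTriple]:
        return [ProbabilityTriple(*row) for row in self.probabilities]


@dataclass(frozen=True)
class ConfusionAnalysis:
    """Confusion matrix, pairwise error vector and confusion score S."""

    triplet: tuple[str, str, str]
    D: np.ndarray
    D_sym: np.ndarray
    error_vector: tuple[float, float, float]
    score: float
    degenerate: bool = False


def triplet_probabilities(
    space: ProfileSpace,
    classes: ClassAssignment,
    triplet: Sequence[str],
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> TernaryResult:
    """Out-of-fold OvR logistic-regression probabilities for a class triplet.

    Training is restricted to the cells of the three classes.  For each
    stratified CV fold, one L2-regularized binary logistic model (liblinear)
    is fit per class on the training cells; held-out cells get the three
    positive-class probabilities, renormalized to sum to 1.
    """
    triplet = tuple(str(t) for t in triplet)
    if len(triplet) != 3 or len(set(triplet)) != 3:
        raise ValueError("triplet must be three distinct class labels")
    labels = np.asarray(classes.labels_for(space.cell_ids))
    idx = np.flatnonzero(np.isin(labels, triplet))
    sub_labels = labels[idx]
    for t in triplet:
        size = int((sub_labels == t).sum())
        if size < folds:
            raise ValidationError(
                f"class {t!r} has {size} cells; need >= {folds} for {folds}-fold CV"
            )
    X = space.vectors[idx]
    probs = np.zeros((idx.size, 3))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in cv.split(X, sub_labels):
        for col, t in enumerate(triplet):
            # liblinear with default L2 penalty, strength 1/C
            model = LogisticRegression(C=C, solver="liblinear", random_state=seed)
            model.fit(X[train], (sub_labels[train] == t).astype(int))
            probs[test, col] = model.predict_proba(X[test])[:, 1]
    probs = probs / probs.sum(axis=1, keepdims=True)
    return TernaryResult(
        triplet=triplet,
        cell_ids=tuple(space.cell_ids[i] for i in idx),
        true_labels=tuple(sub_labels),
        probabilities=probs,
    )


def ternary_coordinates(triple: Sequence[float]) -> tuple[float, float]:
    """Cartesian coordinates of (a, b, c) in the unit-side equilateral
    triangle with a=100% at (0,0), b=100% at (1,0), c=100% at (1/2, sqrt3/2):

        ( 1/2 (2b + c)/(a + b + c),  sqrt3/2 c/(a + b + c) )
    """
    a, b, c = (float(v) for v in triple)
    total = a + b + c
    if total <= 0:
        raise ValueError("probability triple must have positive sum")
    return (0.5 * (2.0 * b + c) / total, 0.5 * SQRT3 * c / total)


def confusion_analysis(
    triples: Sequence[Sequence[float]] | np.ndarray,
    true_labels: Sequence[str],
    triplet: Sequence[str] | None = None,
    symmetrization: Literal["mean", "product"] = "mean",
) -> ConfusionAnalysis:
    """Class-averaged confusion matrix and confusion score for a triplet.

    ``D[r, j]`` is the mean probability of class ``j`` over cells whose true
    class is ``r`` (classes ordered as in ``triplet``; inferred from label
    appearance order when omitted).  ``symmetrization="mean"`` uses
    (D + D^T)/2; ``"product"`` uses D D^T / 2 (a literal alternative kept
    for comparison).  The score is min(E) over the sum of the other two
    pairwise errors; if that denominator is 0 the analysis is flagged
    degenerate and the score reported as 0.
    """
    P = np.asarray(triples, dtype=float)
    labels = np.asarray([str(t) for t in true_labels])
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] != labels.size:
        raise ValueError("need an n x 3 probability array aligned with labels")
    if triplet is None:
        seen: dict[str, None] = {}
        for lab in labels:
            seen.setdefault(lab, None)
        triplet = tuple(seen)
    triplet = tuple(str(t) for t in triplet)
    if len(triplet) != 3:
        raise ValueError("triplet must have exactly three classes")
    D = np.zeros((3, 3))
    for r, t in enumerate(triplet):
        mask = labels == t
        if not mask.any():
            raise ValidationError(f"no cells labeled {t!r}")
        D[r] = P[mask].mean(axis=0)
    if symmetrization == "mean":
        D_sym = (D + D.T) / 2.0
    elif symmetrization == "product":
        D_sym = D @ D.T / 2.0
    else:
        raise ValueError(f"unknown symmetrization {symmetrization!r}")
    E = (float(D_sym[0, 1]), float(D_sym[0, 2]), float(D_sym[1, 2]))
    m = int(np.argmin(E))
    denom = sum(E[i] for i in range(3) if i != m)
    if denom <= 0:
        return ConfusionAnalysis(triplet, D, D_sym, E, 0.0, degenerate=True)
    return ConfusionAnalysis(triplet, D, D_sym, E, E[m] / denom, degenerate=False)


def transition_call(
    analysis: ConfusionAnalysis, threshold: float = 0.3
) -> Literal["transition", "no_transition"]:
    """Call a transition when the confusion score is strictly below the
    threshold (a small score means one class pair is cleanly separated
    while both other pairs are confused)."""
    if analysis.degenerate:
        raise ValidationError("degenerate confusion analysis: no transition call")
    return "transition" if analysis.score < threshold else "no_transition"


def analyze_triplet(
    space: ProfileSpace,
    classes: ClassAssignment,
    triplet: Sequence[str],
    folds: int = 5,
    seed: int = 0,
    symmetrization: Literal["mean", "product"] = "mean",
    threshold: float = 0.3,
) -> tuple[TernaryResult, ConfusionAnalysis, str]:
    """Convenience wrapper: probabilities, confusion analysis and call."""
    result = triplet_probabilities(space, classes, triplet, folds=folds, seed=seed)
    analysis = confusion_analysis(
        result.probabilities, result.true_labels, result.triplet, symmetrization
    )
    call = "degenerate" if analysis.degenerate else transition_call(analysis, threshold)
    return result, analysis, call
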