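"""Pairwise species separation in Gene Space with a linear max-margin model.

Genes from two organisms are separated by a hyperplane fitted with a
linear-kernel support vector machine.  Accuracy is estimated with a
split-half swap protocol: each organism's gene set is split into two
disjoint halves, the model is trained on one half of each organism and
scored on the pooled other halves, the roles are swapped, and the two
per-split accuracies are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .core import GeneMatrix, GeneVector, Level


@dataclass(frozen=True)
class SeparatorModel:
    """A fitted linear two-class boundary.

    decision(x) = weights . x + offset; positive side = first organism.
    """

    weights: np.ndarray
    offset: float
    vocab_level: Level
    organisms: tuple[str, str]

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.weights.shape[0]:
            raise ValueError(
                f"dimension mismatch: {X.shape[1]} vs {self.weights.shape[0]}"
            )
        return X @ self.weights + self.offset

    def predict_first(self, X: np.ndarray) -> np.ndarray:
        """True where a point is assigned to the first organism.

        Points exactly on the boundary (decision value 0) are deliberately
        assigned to neither class by the scoring code; here they fall on the
        second-organism side, and the scorer handles the tie explicitly.
        """
        return self.decision(X) > 0


@dataclass(frozen=True)
class SeparationResults:
    """Swap-averaged correct-identification probability for a pair.

    ``accuracy`` is the mean of the two per-split values: the pooled
    fraction of held-out genes assigned to their true organism.
    """

    organisms: tuple[str, str]
    level: Level
    accuracy: float
    per_split_accuracies: tuple[float, float]
    seed: int
    n_genes: tuple[int, int]

    def summary(self) -> str:
        a, b = self.organisms
        s1, s2 = self.per_split_accuracies
        lines = [
            "Gene separation (linear max-margin, split-half swap)",
            "====================================================",
            f"organisms:        {a} vs {b}",
            f"token level:      {self.level}",
            f"genes:            {self.n_genes[0]} / {self.n_genes[1]}",
            f"seed:             {self.seed}",
            f"split accuracies: {s1:.4f}, {s2:.4f}",
            f"accuracy:         {self.accuracy:.4f}",
        ]
        return "\n".join(lines)


def split_half(m: GeneMatrix, seed: int) -> tuple[GeneMatrix, GeneMatrix]:
    """Randomly split a gene set into two disjoint near-equal halves.

    With an odd count the extra gene goes to the first half.  The same seed
    always yields the same partition.
    """
    if m.n_genes < 2:
        raise ValueError("need at least 2 genes to split in half")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m.n_genes)
    cut = (m.n_genes + 1) // 2
    return m.subset(perm[:cut]), m.subset(perm[cut:])


def train_separator(a: GeneMatrix, b: GeneMatrix, C: float = 1.0,
                    tol: float = 1e-6) -> SeparatorModel:
    """Fit the linear boundary between two organisms' gene clouds."""
    if a.vocab.level != b.vocab.level or a.vocab.n != b.vocab.n:
        raise ValueError("both matrices must share one vocabulary")
    if a.n_genes == 0 or b.n_genes == 0:
        raise ValueError("both matrices must be non-empty")
    X = np.vstack([a.X, b.X])
    # first organism = class 1 so the decision function is positive for it
    y = np.concatenate([np.ones(a.n_genes), np.zeros(b.n_genes)])
    clf = SVC(kernel="linear", C=C, tol=tol)
    clf.fit(X, y)
    return SeparatorModel(
        weights=clf.coef_.ravel().copy(),
        offset=float(clf.intercept_[0]),
        vocab_level=a.vocab.level,
        organisms=(a.organism, b.organism),
    )


def _score_half(model: SeparatorModel, test_a: GeneMatrix,
                test_b: GeneMatrix, balanced: bool) -> float:
    """Fraction of held-out genes assigned to their true organism.

    Ties at the decision boundary count as incorrect for both classes.
    """
    da = model.decision(test_a.X)
    db = model.decision(test_b.X)
    correct_a = int(np.sum(da > 0))
    correct_b = int(np.sum(db < 0))
    if balanced:
        return 0.5 * (correct_a / test_a.n_genes + correct_b / test_b.n_genes)
    return (correct_a + correct_b) / (test_a.n_genes + test_b.n_genes)


class GeneSeparator:
    """Model object for pairwise organism separation.

    Parameters
    ----------
    a, b : GeneMatrix
        The two organisms' gene clouds in one Gene Space.
    C : float
        Soft-margin regularization constant of the linear max-margin fit.
    balanced : bool
        If True, accuracy is the macro average of the two per-organism
        correct fractions rather than the pooled fraction.
    """

    def __init__(self, a: GeneMatrix, b: GeneMatrix, C: float = 1.0,
                 balanced: bool = False) -> None:
        if a.vocab.level != b.vocab.level:
            raise ValueError("both matrices must share one vocabulary level")
        if a.n_genes < 4 or b.n_genes < 4:
            raise ValueError("each organism needs at least 4 genes")
        self.a = a
        self.b = b
        self.C = C
        self.balanced = balanced

    def fit(self, seed: int = 17) -> SeparationResults:
        """Run the full split-half swap protocol and average the results."""
        a1, a2 = split_half(self.a, seed)
        b1, b2 = split_half(self.b, seed)
        accs = []
        for train, test in (((a1, b1), (a2, b2)), ((a2, b2), (a1, b1))):
            model = train_separator(train[0], train[1], C=self.C)
            accs.append(_score_half(model, test[0], test[1], self.balanced))
        return SeparationResults(
            organisms=(self.a.organism, self.b.organism),
            level=self.a.vocab.level,
            accuracy=float(np.mean(accs)),
            per_split_accuracies=(accs[0], accs[1]),
            seed=seed,
            n_genes=(self.a.n_genes, self.b.n_genes),
        )


def separation_accuracy(a: GeneMatrix, b: GeneMatrix, seed: int = 17,
                        C: float = 1.0,
                        balanced: bool = False) -> SeparationResults:
    """Split-half swap-averaged separation accuracy for one organism pair."""
    return GeneSeparator(a, b, C=C, balanced=balanced).fit(seed)


def pairwise_separation(matrices: Sequence[GeneMatrix], seed: int = 17,
                        C: float = 1.0) -> pd.DataFrame:
    """All-pairs separation table for organisms in one Gene Space.

    Returns a symmetric organism x organism DataFrame with NaN on the
    diagonal, suitable for TSV serialization.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 organisms")
    labels = [m.organism for m in matrices]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate organism labels")
    table = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i in range(len(matrices)):
        for j in range(i + 1, len(matrices)):
            res = separation_accuracy(matrices[i], matrices[j], seed=seed, C=C)
            table.iloc[i, j] = res.accuracy
            table.iloc[j, i] = res.accuracy
    return table
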