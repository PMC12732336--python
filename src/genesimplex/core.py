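"""Gene Space geometry: token vocabularies, simplex embedding, distances.

A gene is represented by the frequencies of its tokens — single nucleotides,
in-frame codons, or adjacent codon pairs.  Because frequencies are
normalized to sum to 1, the set of attainable points is the standard
(n-1)-dimensional probability simplex with n vertices, one per token; this
simplex is the Gene Space.  Only the 61 sense codons are admissible token
components, so n = 4, 61 and 3721 at the three levels.

All geometry here is exact Euclidean geometry on the simplex:

* the center is the barycenter (every coordinate 1/n), representing a
  sequence using all tokens equally;
* each vertex is the indicator vector of one token, representing a sequence
  composed of that token alone;
* any two distinct vertices are sqrt(2) apart, and the center-to-vertex
  distance is sqrt((n-1)/n), which is the maximal distance from the center
  and approaches 1 as n grows.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .seqio import (BASES, LEVELS, STOP_CODONS, CdsRecord, Level,
                    ValidationPolicy, DEFAULT_POLICY, validate_cds)

logger = logging.getLogger(__name__)

PairMode = Literal["sliding", "disjoint"]

#: The 61 sense codons in lexicographic order — the fixed codon axis order.
SENSE_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(BASES, repeat=3)
    if "".join(c) not in STOP_CODONS
)


@dataclass(frozen=True)
class TokenVocabulary:
    """Ordered token set defining the axes of one Gene Space.

    Axis order is lexicographic over token strings — a fixed function of the
    level, so embeddings are bit-reproducible across runs.
    """

    level: Level
    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {t: i for i, t in enumerate(self.tokens)}
        )

    @property
    def n(self) -> int:
        """Number of axes / simplex vertices."""
        return len(self.tokens)

    def index(self, token: str) -> int:
        try:
            return self._index[token]
        except KeyError:
            raise KeyError(
                f"token {token!r} is not an axis of the {self.level} vocabulary"
            ) from None

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __len__(self) -> int:
        return self.n


def build_vocabulary(level: Level) -> TokenVocabulary:
    """Deterministic vocabulary for a tokenization level.

    nucleotide -> 4 bases; codon -> the 61 sense codons (64 triplets minus
    TAA/TAG/TGA); codon_pair -> all 61*61 = 3721 ordered sense-codon pairs.
    """
    if level == "nucleotide":
        tokens: tuple[str, ...] = BASES
    elif level == "codon":
        tokens = SENSE_CODONS
    elif level == "codon_pair":
        tokens = tuple(a + b for a in SENSE_CODONS for b in SENSE_CODONS)
    else:
        raise ValueError(f"unknown tokenization level: {level!r}")
    return TokenVocabulary(level=level, tokens=tokens)


@dataclass(frozen=True)
class GeneVector:
    """One gene's point in Gene Space: normalized token frequencies."""

    gene_id: str
    coords: np.ndarray
    n_tokens: int

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if self.n_tokens < 1:
            raise ValueError("GeneVector needs at least one contributing token")
        if np.any(coords < 0):
            raise ValueError("token frequencies must be non-negative")
        if abs(coords.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"token frequencies of {self.gene_id!r} sum to {coords.sum()!r}, not 1"
            )

    @property
    def n(self) -> int:
        return self.coords.shape[0]


class GeneMatrix:
    """A set of genes from one organism embedded in a shared Gene Space.

    Stores coordinates as a dense (n_genes, n) array for the fitting code,
    with per-gene ids and token counts alongside.
    """

    def __init__(self, organism: str, vocab: TokenVocabulary,
                 X: np.ndarray, gene_ids: Sequence[str],
                 n_tokens: Optional[Sequence[int]] = None) -> None:
        if not organism:
            raise ValueError("organism label must be non-empty")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != vocab.n:
            raise ValueError(
                f"coordinate array must be (n_genes, {vocab.n}); got {X.shape}"
            )
        if len(gene_ids) != X.shape[0]:
            raise ValueError("gene_ids length must match coordinate rows")
        self.organism = organism
        self.vocab = vocab
        self.X = X
        self.gene_ids = list(gene_ids)
        self.n_tokens = (list(n_tokens) if n_tokens is not None
                         else [1] * X.shape[0])

    @classmethod
    def from_vectors(cls, organism: str, vocab: TokenVocabulary,
                     vectors: Sequence[GeneVector]) -> "GeneMatrix":
        if not vectors:
            raise ValueError("cannot build a GeneMatrix from zero vectors")
        X = np.stack([v.coords for v in vectors])
        return cls(organism, vocab, X,
                   [v.gene_id for v in vectors],
                   [v.n_tokens for v in vectors])

    @property
    def vectors(self) -> list[GeneVector]:
        return [GeneVector(g, self.X[i], self.n_tokens[i])
                for i, g in enumerate(self.gene_ids)]

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    def subset(self, idx: Sequence[int]) -> "GeneMatrix":
        idx = list(idx)
        return GeneMatrix(self.organism, self.vocab, self.X[idx],
                          [self.gene_ids[i] for i in idx],
                          [self.n_tokens[i] for i in idx])

    def __len__(self) -> int:
        return self.n_genes

    def to_frame(self) -> pd.DataFrame:
        """TSV-friendly table: gene_id + one column per token, axis order."""
        df = pd.DataFrame(self.X, columns=list(self.vocab.tokens))
        df.insert(0, "gene_id", self.gene_ids)
        return df


def embed(tokens: Sequence[Optional[str]], vocab: TokenVocabulary,
          gene_id: str = "gene", pair_mode: PairMode = "sliding") -> GeneVector:
    """Embed a validated token stream as a point in Gene Space.

    Coordinates are occurrence counts divided by the total token count.  At
    codon-pair level the input is the in-frame codon stream (``None`` marks
    a skipped position) and pairs are formed over adjacent codons — by
    default a sliding window advancing one codon per step, so a gene of L
    codons yields L-1 candidate pairs; ``pair_mode='disjoint'`` instead
    takes non-overlapping pairs (0,1), (2,3), ...  Pairs touching a skipped
    position are never counted.

    Raises
    ------
    ValueError
        If no countable token remains (the gene is unusable at this level).
    """
    counts = np.zeros(vocab.n, dtype=float)
    if vocab.level == "codon_pair":
        step = 1 if pair_mode == "sliding" else 2
        if pair_mode not in ("sliding", "disjoint"):
            raise ValueError(f"unknown pair_mode: {pair_mode!r}")
        for i in range(0, len(tokens) - 1, step):
            a, b = tokens[i], tokens[i + 1]
            if a is None or b is None:
                continue
            pair = a + b
            if pair in vocab:
                counts[vocab.index(pair)] += 1
    else:
        for t in tokens:
            if t is not None and t in vocab:
                counts[vocab.index(t)] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError(
            f"gene {gene_id!r} has no countable tokens at level {vocab.level!r}"
        )
    return GeneVector(gene_id=gene_id, coords=counts / total,
                      n_tokens=int(total))


def embed_records(records: Iterable[CdsRecord], vocab: TokenVocabulary,
                  organism: str,
                  policy: ValidationPolicy = DEFAULT_POLICY,
                  pair_mode: PairMode = "sliding") -> GeneMatrix:
    """Validate and embed a set of CDS records into one GeneMatrix.

    Genes rejected by the policy, or with zero countable tokens at this
    level, are dropped with a logged warning (reason included).
    """
    vectors: list[GeneVector] = []
    n_rejected = 0
    for rec in records:
        outcome = validate_cds(rec, policy, vocab.level)
        if not outcome.ok:
            n_rejected += 1
            logger.warning("gene %s rejected at %s level: %s",
                           rec.id, vocab.level, outcome.reason)
            continue
        try:
            vectors.append(embed(outcome.tokens, vocab, rec.id, pair_mode))
        except ValueError:
            n_rejected += 1
            logger.warning("gene %s has no countable tokens at %s level",
                           rec.id, vocab.level)
    if not vectors:
        raise ValueError(
            f"no genes of {organism!r} survived validation at {vocab.level!r}"
        )
    if n_rejected:
        logger.info("%s: %d genes rejected, %d embedded at %s level",
                    organism, n_rejected, len(vectors), vocab.level)
    return GeneMatrix.from_vectors(organism, vocab, vectors)


def center(vocab: TokenVocabulary) -> GeneVector:
    """Barycenter of the simplex: every token at frequency 1/n."""
    n = vocab.n
    return GeneVector("center", np.full(n, 1.0 / n), n_tokens=n)


def vertex(vocab: TokenVocabulary, token: str) -> GeneVector:
    """Indicator vector for one token — a simplex corner."""
    coords = np.zeros(vocab.n)
    coords[vocab.index(token)] = 1.0
    return GeneVector(f"vertex:{token}", coords, n_tokens=1)


def distance(a: Union[GeneVector, np.ndarray],
             b: Union[GeneVector, np.ndarray]) -> float:
    """Euclidean distance between two points of the same Gene Space."""
    xa = a.coords if isinstance(a, GeneVector) else np.asarray(a, dtype=float)
    xb = b.coords if isinstance(b, GeneVector) else np.asarray(b, dtype=float)
    if xa.shape != xb.shape:
        raise ValueError(f"dimension mismatch: {xa.shape} vs {xb.shape}")
    return float(np.linalg.norm(xa - xb))


def max_center_distance(n: int) -> float:
    """Center-to-vertex distance sqrt((n-1)/n): the largest distance from
    the barycenter attainable within the simplex. Tends to 1 as n grows."""
    return float(np.sqrt((n - 1) / n))


def center_distance(v: Union[GeneVector, np.ndarray], vocab: TokenVocabulary,
                    normalized: bool = False) -> float:
    """Distance from a gene to the Gene Space center.

    With ``normalized=True`` the distance is divided by the center-to-vertex
    distance sqrt((n-1)/n), so vertices map to exactly 1.  This measures the
    inequality of token usage: 0 = perfectly uniform, 1 = a single token.
    """
    x = v.coords if isinstance(v, GeneVector) else np.asarray(v, dtype=float)
    if x.shape[0] != vocab.n:
        raise ValueError(
            f"vector dimension {x.shape[0]} != vocabulary size {vocab.n}"
        )
    d = float(np.linalg.norm(x - 1.0 / vocab.n))
    if normalized:
        d /= max_center_distance(vocab.n)
    return d


def distance_distribution(m: GeneMatrix,
                          normalized: bool = False) -> pd.DataFrame:
    """Per-gene distances to the Gene Space center, one row per gene.

    Row order matches the matrix.  This is the basis for comparing how far
    from uniform token usage each organism's genes sit.
    """
    if m.n_genes == 0:
        raise ValueError("empty GeneMatrix")
    diffs = m.X - 1.0 / m.vocab.n
    d = np.linalg.norm(diffs, axis=1)
    if normalized:
        d = d / max_center_distance(m.vocab.n)
    return pd.DataFrame({"gene_id": m.gene_ids, "distance": d})
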