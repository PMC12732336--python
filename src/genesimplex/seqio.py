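"""Reading, validating and writing coding sequences (CDS).

The embedding machinery in :mod:`genesimplex.core` operates on clean token
streams; this module is the boundary between raw FASTA files and those
streams.  A :class:`ValidationPolicy` controls how real-world CDS quirks
(lengths not divisible by three, internal stop codons, ambiguity codes) are
handled before any counting happens.  Stop codons are never emitted as
countable tokens: the codon vocabulary is restricted to the 61 sense codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
BASES = ("A", "C", "G", "T")

Level = Literal["nucleotide", "codon", "codon_pair"]
LEVELS: tuple[Level, ...] = ("nucleotide", "codon", "codon_pair")

TokenAction = Literal["skip_token", "reject_gene"]


@dataclass(frozen=True)
class CdsRecord:
    """A single coding sequence.

    Attributes
    ----------
    id : str
        Sequence identifier (non-empty).
    seq : str
        Nucleotide string, stored uppercase.
    source : str
        Origin of the record: a file path, or ``"synthetic"``.
    """

    id: str
    seq: str
    source: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("CdsRecord id must be non-empty")
        if not self.seq:
            raise ValueError(f"CdsRecord {self.id!r} has an empty sequence")
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ValidationPolicy:
    """How a CDS is cleaned before token counting.

    Defaults follow the convention of counting only amino-acid-encoding
    codons: the terminal stop is stripped, and any token containing a stop
    codon or an ambiguous base is skipped rather than the whole gene being
    discarded.
    """

    require_triplet: bool = True
    strip_terminal_stop: bool = True
    ambiguous_token_action: TokenAction = "skip_token"
    internal_stop_action: TokenAction = "skip_token"
    min_tokens: int = 10

    def __post_init__(self) -> None:
        if self.min_tokens < 1:
            raise ValueError("min_tokens must be >= 1")
        for name in ("ambiguous_token_action", "internal_stop_action"):
            if getattr(self, name) not in ("skip_token", "reject_gene"):
                raise ValueError(f"{name} must be 'skip_token' or 'reject_gene'")


DEFAULT_POLICY = ValidationPolicy()


@dataclass(frozen=True)
class ValidationOutcome:
    """Result of :func:`validate_cds`: a token stream or a rejection.

    ``tokens`` is a list of bases (nucleotide level) or codons (codon and
    codon-pair levels).  At codon-pair level, positions whose codon was
    skipped under the policy are kept as ``None`` sentinels so that only
    genuinely adjacent codons are ever paired downstream.
    """

    tokens: Optional[list[Optional[str]]]
    reason: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.reason is None

    @property
    def n_countable(self) -> int:
        if self.tokens is None:
            return 0
        return sum(1 for t in self.tokens if t is not None)


def read_fasta(path: Union[str, Path]) -> list[CdsRecord]:
    """Read a (multi-)FASTA file into :class:`CdsRecord` objects.

    Records are returned in file order with sequences uppercased; nothing
    else is mutated.  A missing file raises :class:`FileNotFoundError`;
    sequence data appearing before the first header raises ``ValueError``
    naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    _check_leading_sequence(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(CdsRecord(id=rec.id, seq=str(rec.seq), source=str(path)))
    return records


def _check_leading_sequence(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                return
            raise ValueError(
                f"malformed FASTA {path}: sequence before first header at line {lineno}"
            )


def write_fasta(records: Iterable[CdsRecord], path: Union[str, Path],
                wrap: int = 60) -> None:
    """Write records to FASTA. Inverse of :func:`read_fasta` on (id, seq)."""
    seq_records = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seq_records)


def _codon_ok(codon: str) -> tuple[bool, Optional[str]]:
    """Classify a codon: (countable, problem) with problem in
    {None, 'stop', 'ambiguous'}."""
    if any(b not in BASES for b in codon):
        return False, "ambiguous"
    if codon in STOP_CODONS:
        return False, "stop"
    return True, None


def validate_cds(rec: CdsRecord, policy: ValidationPolicy = DEFAULT_POLICY,
                 level: Level = "codon") -> ValidationOutcome:
    """Apply a cleaning policy to one CDS and return its token stream.

    At ``nucleotide`` level the stream is the base list (ambiguous bases
    handled per policy).  At ``codon`` and ``codon_pair`` levels the
    sequence is read in the annotated frame (position 0), a terminal stop
    is stripped if flagged, and codons containing stops or ambiguous bases
    are skipped or cause gene rejection per policy.  Rejection is a return
    state (machine-readable ``reason``), never an exception.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown tokenization level: {level!r}")
    seq = rec.seq

    if level == "nucleotide":
        tokens: list[Optional[str]] = []
        for base in seq:
            if base in BASES:
                tokens.append(base)
            elif policy.ambiguous_token_action == "reject_gene":
                return ValidationOutcome(None, "ambiguous_base")
        if len(tokens) < policy.min_tokens:
            return ValidationOutcome(None, "too_few_tokens")
        return ValidationOutcome(tokens)

    if policy.require_triplet and len(seq) % 3 != 0:
        return ValidationOutcome(None, "length_not_multiple_of_3")
    n_codons = len(seq) // 3
    codons = [seq[3 * i: 3 * i + 3] for i in range(n_codons)]
    if policy.strip_terminal_stop and codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    if not codons:
        return ValidationOutcome(None, "too_few_tokens")

    out: list[Optional[str]] = []
    for codon in codons:
        countable, problem = _codon_ok(codon)
        if countable:
            out.append(codon)
            continue
        action = (policy.internal_stop_action if problem == "stop"
                  else policy.ambiguous_token_action)
        if action == "reject_gene":
            reason = "internal_stop" if problem == "stop" else "ambiguous_base"
            return ValidationOutcome(None, reason)
        # skip_token: codon level drops the position entirely; codon_pair
        # level keeps a sentinel so downstream pairing stays adjacency-true.
        if level == "codon_pair":
            out.append(None)

    n_countable = sum(1 for t in out if t is not None)
    if n_countable < policy.min_tokens:
        return ValidationOutcome(None, "too_few_tokens")
    return ValidationOutcome(out)
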