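"""DNA alphabet, IUPAC degeneracy, reverse complement and FASTA ingest.

All downstream stages (PAM scanning, density statistics, guide design,
indel calling) share the conventions fixed here: sequences are uppercase
strings over ``{A, C, G, T, N}``, and a genomic ``N`` — an ambiguous
assembly base — matches *no* pattern position, including the pattern
wildcard ``N``.  An ambiguous base is not a designable target.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, TextIO

__all__ = [
    "IUPAC_SETS",
    "SeqRecord",
    "IupacPattern",
    "FastaParseError",
    "parse_fasta",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "matches_pattern",
]

#: Standard IUPAC nucleotide code: symbol -> set of concrete bases.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SEQ_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaParseError(ValueError):
    """Malformed FASTA input; carries the 1-based offending line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class SeqRecord:
    """A named DNA sequence (uppercase, alphabet ``{A,C,G,T,N}``)."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class IupacPattern:
    """A degenerate nucleotide motif, e.g. the SaCas9 PAM ``NNGRRT``.

    ``allowed_sets[i]`` is the set of concrete bases accepted at
    position ``i``.  Patterns are validated at construction; the IUPAC
    table is fixed to the standard nucleotide code.
    """

    name: str
    symbols: str
    allowed_sets: tuple[frozenset[str], ...] = field(compare=False)

    def __post_init__(self):
        if len(self.symbols) < 1:
            raise ValueError("pattern must have length >= 1")
        if len(self.allowed_sets) != len(self.symbols):
            raise ValueError("allowed_sets length must match symbols")
        for s in self.allowed_sets:
            if not s:
                raise ValueError("empty allowed set")

    @classmethod
    def from_string(cls, pattern: str, name: str | None = None) -> "IupacPattern":
        pattern = pattern.upper()
        try:
            sets = tuple(IUPAC_SETS[sym] for sym in pattern)
        except KeyError as exc:
            raise ValueError(f"not an IUPAC nucleotide code: {exc.args[0]!r}") from None
        return cls(name=name or pattern, symbols=pattern, allowed_sets=sets)

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def degeneracy(self) -> int:
        """Number of concrete ACGT words matching the pattern."""
        n = 1
        for s in self.allowed_sets:
            n *= len(s)
        return n


def _validate_sequence(seq: str, line_number: int) -> None:
    bad = set(seq) - _SEQ_ALPHABET
    if bad:
        raise FastaParseError(
            f"illegal sequence character(s) {sorted(bad)!r}", line_number
        )


def parse_fasta(stream: TextIO | Iterable[str] | str) -> list[SeqRecord]:
    """Parse multi-record FASTA text into :class:`SeqRecord` objects.

    Sequences are uppercased on ingest (soft-masked lowercase regions are
    not treated specially) and restricted to ``{A,C,G,T,N}``.  Wrapped
    and unwrapped sequence lines are both accepted.

    Raises :class:`FastaParseError` naming the line number on a
    malformed header or an illegal character.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[SeqRecord] = []
    current_id: str | None = None
    chunks: list[str] = []

    def flush():
        if current_id is not None:
            records.append(SeqRecord(id=current_id, sequence="".join(chunks)))

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            if not header:
                raise FastaParseError("empty FASTA header", lineno)
            current_id = header.split()[0]
            chunks = []
        else:
            if current_id is None:
                raise FastaParseError("sequence data before first '>' header", lineno)
            seq = line.strip().upper()
            _validate_sequence(seq, lineno)
            chunks.append(seq)
    flush()
    return records


def read_fasta(path) -> list[SeqRecord]:
    """Read a FASTA file from ``path``."""
    with open(path) as fh:
        return parse_fasta(fh)


def write_fasta(records: Iterable[SeqRecord], stream: TextIO, width: int = 70) -> None:
    """Write records as FASTA with lines wrapped at ``width`` columns."""
    for rec in records:
        stream.write(f">{rec.id}\n")
        for i in range(0, len(rec.sequence), width):
            stream.write(rec.sequence[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement over ``{A,C,G,T,N}``; ``N`` is self-complementary."""
    seq = seq.upper()
    bad = set(seq) - _SEQ_ALPHABET
    if bad:
        raise ValueError(f"illegal character(s) for reverse complement: {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def matches_pattern(window: str, pattern: IupacPattern) -> bool:
    """True iff every base of ``window`` lies in the pattern's allowed set.

    The *genomic* base ``N`` matches nothing — not even pattern ``N`` —
    so windows over ambiguous assembly bases are never reported.
    """
    if len(window) != len(pattern):
        raise ValueError(
            f"window length {len(window)} != pattern length {len(pattern)}"
        )
    return all(b in s for b, s in zip(window.upper(), pattern.allowed_sets))
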