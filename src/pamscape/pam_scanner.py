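"""Enumerate CRISPR target sites for degenerate PAM classes on both strands.

A target site is a protospacer (default 20 bp, the guide-matched genomic
sequence) immediately 5' of a PAM match *on the targeted strand*.  Matches
on the reverse strand are mapped back to forward 0-based half-open
coordinates, so a BED line can be emitted for either strand.  Overlapping
and dyad-symmetric sites are all reported; windows touching an ambiguous
genomic ``N`` are suppressed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from .sequence_core import IupacPattern, SeqRecord, reverse_complement

__all__ = [
    "PAM_CLASSES",
    "PamSpec",
    "TargetSite",
    "SiteTable",
    "scan_record",
    "scan_genome",
    "write_bed",
    "parse_bed_sites",
]

#: The six PAM classes routinely scanned: SpCas9 (NGG), VQR SpCas9 (NGA),
#: SaCas9 relaxed/strict (NNGRRN / NNGRRT), KKH SaCas9 relaxed/strict
#: (NNNRRN / NNNRRT).
PAM_CLASSES: tuple[str, ...] = ("NGG", "NGA", "NNGRRN", "NNGRRT", "NNNRRN", "NNNRRT")


@dataclass(frozen=True)
class PamSpec:
    """A PAM class to scan for: pattern plus protospacer length."""

    class_name: str
    pattern: IupacPattern
    spacer_length: int = 20

    def __post_init__(self):
        if self.spacer_length < 1:
            raise ValueError("spacer_length must be >= 1")
        if len(self.pattern) < 2:
            raise ValueError("PAM pattern must have length >= 2")

    @classmethod
    def from_name(cls, class_name: str, spacer_length: int = 20) -> "PamSpec":
        """Build a spec whose pattern string is the class name itself."""
        return cls(
            class_name=class_name,
            pattern=IupacPattern.from_string(class_name),
            spacer_length=spacer_length,
        )


@dataclass(frozen=True)
class TargetSite:
    """One candidate CRISPR site in forward 0-based half-open coordinates.

    ``protospacer_seq`` and ``pam_seq`` are read on the *targeted* strand:
    for a ``-`` site they are reverse complements of the forward-strand
    slice.  On ``+`` the PAM abuts the protospacer's 3' end
    (``pam_start == protospacer_end``); on ``-`` the forward-coordinate
    PAM interval sits immediately left (``pam_end == protospacer_start``).
    """

    record_id: str
    strand: str
    protospacer_start: int
    protospacer_end: int
    pam_start: int
    pam_end: int
    protospacer_seq: str
    pam_seq: str
    pam_class: str

    @property
    def start(self) -> int:
        """Leftmost forward coordinate of the protospacer+PAM union."""
        return min(self.protospacer_start, self.pam_start)

    @property
    def end(self) -> int:
        """Rightmost forward coordinate of the protospacer+PAM union."""
        return max(self.protospacer_end, self.pam_end)


@dataclass
class SiteTable:
    """Sites of one scan, sorted by (record_id, start, strand, class)."""

    sites: list[TargetSite] = field(default_factory=list)
    scanned_bp: int = 0


_SORT_KEY = lambda s: (s.record_id, s.start, s.strand, s.pam_class)  # noqa: E731


def _pattern_regex(pattern: IupacPattern) -> re.Pattern:
    # Character classes over concrete bases only: genomic N can never match.
    parts = []
    for allowed in pattern.allowed_sets:
        bases = "".join(sorted(allowed))
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # Lookahead so overlapping matches are all reported.
    return re.compile(f"(?=({''.join(parts)}))")


def scan_record(record: SeqRecord, spec: PamSpec) -> list[TargetSite]:
    """All target sites for one PAM class on both strands of a record.

    A forward match of the PAM at ``[i, i+k)`` with full spacer room
    (``i >= spacer_length``) yields a ``+`` site; matches on the reverse
    complement are remapped to forward coordinates as ``-`` sites.  Sites
    whose protospacer or PAM contains ``N``, or that lack spacer room at
    a record edge, are dropped.
    """
    seq = record.sequence
    k = len(spec.pattern)
    s = spec.spacer_length
    rx = _pattern_regex(spec.pattern)
    sites: list[TargetSite] = []

    def _emit(strand_seq: str, strand: str):
        L = len(strand_seq)
        for m in rx.finditer(strand_seq):
            i = m.start()
            if i < s:
                continue
            protospacer = strand_seq[i - s : i]
            if "N" in protospacer:
                continue
            pam = m.group(1)
            if strand == "+":
                sites.append(
                    TargetSite(
                        record_id=record.id,
                        strand="+",
                        protospacer_start=i - s,
                        protospacer_end=i,
                        pam_start=i,
                        pam_end=i + k,
                        protospacer_seq=protospacer,
                        pam_seq=pam,
                        pam_class=spec.class_name,
                    )
                )
            else:
                # interval [a, b) on the reverse strand maps to [L-b, L-a)
                sites.append(
                    TargetSite(
                        record_id=record.id,
                        strand="-",
                        protospacer_start=L - i,
                        protospacer_end=L - i + s,
                        pam_start=L - i - k,
                        pam_end=L - i,
                        protospacer_seq=protospacer,
                        pam_seq=pam,
                        pam_class=spec.class_name,
                    )
                )

    _emit(seq, "+")
    _emit(reverse_complement(seq), "-")
    sites.sort(key=_SORT_KEY)
    return sites


def scan_genome(
    records: Sequence[SeqRecord], specs: Sequence[PamSpec]
) -> dict[str, SiteTable]:
    """Scan every record for every PAM class; one :class:`SiteTable` per class."""
    names = [sp.class_name for sp in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate PAM class names: {names}")
    scanned_bp = sum(len(r) for r in records)
    out: dict[str, SiteTable] = {}
    for spec in specs:
        sites: list[TargetSite] = []
        for rec in records:
            sites.extend(scan_record(rec, spec))
        sites.sort(key=_SORT_KEY)
        out[spec.class_name] = SiteTable(sites=sites, scanned_bp=scanned_bp)
    return out


def write_bed(table: SiteTable, stream: TextIO, span: str = "union") -> None:
    """Serialize a site table as BED6.

    ``span="union"`` (default) writes the protospacer+PAM union interval —
    the whole editable locus, which is what exon intersection cares
    about; ``span="pam"`` writes the PAM interval only.  The name field
    is ``<pam_class>|<protospacer_seq>|<pam_seq>``, score is 0.
    """
    if span not in ("union", "pam"):
        raise ValueError(f"span must be 'union' or 'pam', got {span!r}")
    for site in table.sites:
        if span == "union":
            start, end = site.start, site.end
        else:
            start, end = site.pam_start, site.pam_end
        name = f"{site.pam_class}|{site.protospacer_seq}|{site.pam_seq}"
        stream.write(
            f"{site.record_id}\t{start}\t{end}\t{name}\t0\t{site.strand}\n"
        )


def parse_bed_sites(stream: Iterable[str]) -> list[tuple[str, int, int, str, int, str]]:
    """Parse BED6 lines back into (chrom, start, end, name, score, strand)."""
    rows = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"line {lineno}: expected >= 6 BED fields")
        chrom, start, end, name, score, strand = fields[:6]
        rows.append((chrom, int(start), int(end), name, int(score), strand))
    return rows
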