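"""Intersect target sites with coding-exon intervals.

Answers the availability question: of all candidate sites for a PAM
class, how many fall in coding exons, where edits actually disrupt gene
function?  Exon strand is recorded but ignored for intersection — a Cas9
site on either strand disrupts the exon it cuts in.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import pandas as pd
from intervaltree import IntervalTree

from .pam_scanner import SiteTable, TargetSite

__all__ = [
    "ExonInterval",
    "AnnotatedSiteTable",
    "parse_intervals",
    "read_intervals",
    "intersect_sites",
    "summarize_availability",
    "write_annotated_bed",
]


@dataclass(frozen=True)
class ExonInterval:
    """An exon in forward 0-based half-open coordinates."""

    record_id: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.name!r}"
            )


@dataclass
class AnnotatedSiteTable:
    """Sites paired with the names of the exons each one overlaps.

    ``per_class_counts`` maps PAM class to ``(total_sites, exonic_sites)``;
    a site is exonic iff its overlap list is non-empty.
    """

    sites: list[tuple[TargetSite, list[str]]] = field(default_factory=list)
    per_class_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    scanned_bp: int = 0
    exon_bp: int = 0


def parse_intervals(
    stream: TextIO | Iterable[str] | str, format: str = "bed"
) -> list[ExonInterval]:
    """Parse exon intervals from BED (3+ columns) or GFF3 text.

    GFF3 coordinates (1-based closed) are converted to 0-based half-open;
    only GFF3 lines whose feature type is ``exon`` are kept, everything
    else is ignored.  Malformed coordinates raise ``ValueError`` naming
    the line number.
    """
    fmt = format.lower()
    if fmt not in ("bed", "gff3"):
        raise ValueError(f"format must be 'bed' or 'gff3', got {format!r}")
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    exons: list[ExonInterval] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        if fmt == "bed":
            if line.startswith(("track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: BED needs >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer BED coordinates") from None
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "."
        else:
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"line {lineno}: GFF3 needs >= 8 columns")
            if fields[2].lower() != "exon":
                continue
            chrom = fields[0]
            try:
                # 1-based closed -> 0-based half-open
                start, end = int(fields[3]) - 1, int(fields[4])
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer GFF3 coordinates") from None
            strand = fields[6] if fields[6] in ("+", "-") else "."
            name = "."
            if len(fields) > 8:
                for kv in fields[8].split(";"):
                    if kv.startswith(("ID=", "Name=")):
                        name = kv.split("=", 1)[1]
                        break
        if end <= start or start < 0:
            raise ValueError(f"line {lineno}: invalid interval [{start}, {end})")
        exons.append(ExonInterval(chrom, start, end, name, strand))
    return exons


def read_intervals(path, format: str | None = None) -> list[ExonInterval]:
    """Read exons from a file, inferring BED vs GFF3 from the extension."""
    if format is None:
        p = str(path).lower()
        format = "gff3" if p.endswith((".gff", ".gff3")) else "bed"
    with open(path) as fh:
        return parse_intervals(fh, format=format)


def _merged_length(exons: Sequence[ExonInterval]) -> int:
    """Total bp covered by the exon set (overlaps counted once), per record."""
    total = 0
    by_rec: dict[str, list[tuple[int, int]]] = {}
    for e in exons:
        by_rec.setdefault(e.record_id, []).append((e.start, e.end))
    for ivs in by_rec.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total


def intersect_sites(
    table: SiteTable,
    exons: Sequence[ExonInterval],
    mode: str = "any_overlap",
) -> AnnotatedSiteTable:
    """Annotate each site with the exons its protospacer+PAM union touches.

    ``any_overlap``: exonic iff >= 1 bp of the union interval overlaps
    >= 1 exon.  ``full_containment``: exonic iff the union interval lies
    entirely within a single exon.  Each overlapping exon is listed once;
    exon input order never affects the result.
    """
    if mode not in ("any_overlap", "full_containment"):
        raise ValueError(f"unknown mode {mode!r}")
    trees: dict[str, IntervalTree] = {}
    for e in exons:
        trees.setdefault(e.record_id, IntervalTree()).addi(e.start, e.end, e)

    annotated: list[tuple[TargetSite, list[str]]] = []
    counts: dict[str, list[int]] = {}
    for site in table.sites:
        hits: list[ExonInterval] = []
        tree = trees.get(site.record_id)
        if tree is not None:
            for iv in tree.overlap(site.start, site.end):
                exon: ExonInterval = iv.data
                if mode == "any_overlap":
                    hits.append(exon)
                elif exon.start <= site.start and site.end <= exon.end:
                    hits.append(exon)
        # deterministic, order-independent listing
        names = [e.name for e in sorted(hits, key=lambda e: (e.start, e.end, e.name))]
        annotated.append((site, names))
        c = counts.setdefault(site.pam_class, [0, 0])
        c[0] += 1
        if names:
            c[1] += 1
    return AnnotatedSiteTable(
        sites=annotated,
        per_class_counts={k: (v[0], v[1]) for k, v in counts.items()},
        scanned_bp=table.scanned_bp,
        exon_bp=_merged_length(exons) if exons else 0,
    )


def summarize_availability(annotated: AnnotatedSiteTable) -> pd.DataFrame:
    """Per-class availability summary.

    Columns: total sites, exonic sites, sites per kb scanned, and sites
    per kb of (merged) exon.  Rows sorted by PAM class name.
    """
    rows = []
    for cls in sorted(annotated.per_class_counts):
        total, exonic = annotated.per_class_counts[cls]
        rows.append(
            {
                "pam_class": cls,
                "total_sites": total,
                "exonic_sites": exonic,
                "sites_per_kb_scanned": (
                    1000.0 * total / annotated.scanned_bp if annotated.scanned_bp else 0.0
                ),
                "exonic_sites_per_kb_exon": (
                    1000.0 * exonic / annotated.exon_bp if annotated.exon_bp else 0.0
                ),
            }
        )
    columns = [
        "pam_class",
        "total_sites",
        "exonic_sites",
        "sites_per_kb_scanned",
        "exonic_sites_per_kb_exon",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_annotated_bed(annotated: AnnotatedSiteTable, stream: TextIO) -> None:
    """BED6 with the name field extended by ``|exonic:<e1,e2>`` for exonic sites."""
    for site, exon_names in annotated.sites:
        name = f"{site.pam_class}|{site.protospacer_seq}|{site.pam_seq}"
        if exon_names:
            name += "|exonic:" + ",".join(exon_names)
        stream.write(
            f"{site.record_id}\t{site.start}\t{site.end}\t{name}\t0\t{site.strand}\n"
        )
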