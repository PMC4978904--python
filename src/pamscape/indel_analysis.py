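"""Indel classification of Sanger alleles and T7E1 mutagenesis estimates.

Each cloned allele is globally aligned to its reference amplicon
(Needleman–Wunsch with affine gaps via Bio.Align); maximal gap runs
become indel events — a gap in the allele row is a deletion, a gap in
the reference row an insertion carrying the inserted bases.  Events are
left-aligned through homopolymer/repeat context (the VCF normalization
convention), so a deletion inside ``AAAA`` is always reported at the
run's left edge.  Substitutions are counted but not treated as events.

The T7E1 endonuclease cleaves heteroduplexes formed when reannealed
amplicons pair a mutant with a wild-type strand.  With indel fraction p
and random reannealing the heteroduplex (cleaved) fraction is
1 - (1-p)^2, inverted by :func:`t7e1_indel_fraction`; both the raw
cleaved fraction and the corrected indel fraction are reported because
published figures vary in which one they quote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from Bio import Align

from .sequence_core import SeqRecord

__all__ = [
    "AlignmentScoring",
    "IndelEvent",
    "AlleleCall",
    "T7E1Estimate",
    "call_indels",
    "summarize_alleles",
    "t7e1_indel_fraction",
]


@dataclass(frozen=True)
class AlignmentScoring:
    """Global alignment parameters (affine gap model).

    Scores, not penalties: gap scores are negative.  ``gap_open``
    applies to the first column of a gap run and ``gap_extend`` to each
    further column, so a length-L gap scores
    ``gap_open + (L-1)*gap_extend``.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class IndelEvent:
    """One insertion or deletion relative to the reference amplicon."""

    kind: str  # "insertion" | "deletion"
    ref_position: int  # 0-based position in the reference
    length: int
    inserted_seq: str = ""

    @property
    def signed_length(self) -> int:
        return self.length if self.kind == "insertion" else -self.length


@dataclass
class AlleleCall:
    """Indel events of one sequenced allele vs its reference."""

    allele_id: str
    events: list[IndelEvent] = field(default_factory=list)
    net_change: int = 0
    multiplicity: int = 1
    substitutions: int = 0


@dataclass(frozen=True)
class T7E1Estimate:
    """Cleaved band fraction and the derived indel fraction."""

    cleaved_fraction: float
    indel_fraction: float


def _build_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _left_align(event: IndelEvent, ref: str) -> IndelEvent:
    """Shift an event leftward while the flanking context permits.

    A deletion of ``ref[p:p+L]`` may move to ``p-1`` when
    ``ref[p-1] == ref[p+L-1]``; an insertion moves left when its last
    base equals the reference base before the insertion point (rotating
    the inserted string).  This is the standard VCF left-normalization.
    """
    p = event.ref_position
    if event.kind == "deletion":
        L = event.length
        while p > 0 and ref[p - 1] == ref[p + L - 1]:
            p -= 1
        return IndelEvent("deletion", p, L)
    ins = event.inserted_seq
    while p > 0 and ins and ref[p - 1] == ins[-1]:
        ins = ref[p - 1] + ins[:-1]
        p -= 1
    return IndelEvent("insertion", p, event.length, ins)


def call_indels(
    reference: SeqRecord,
    allele: SeqRecord,
    scoring: AlignmentScoring | None = None,
) -> AlleleCall:
    """Classify the indels of one allele against its reference amplicon.

    End-to-end global alignment; ties are resolved deterministically by
    the aligner and events are then left-aligned, so equivalent gap
    placements collapse to one canonical call.  Substitution-only
    alleles come back with zero events and a substitution count.
    """
    scoring = scoring or AlignmentScoring()
    if not reference.sequence or not allele.sequence:
        raise ValueError("reference and allele must be non-empty")
    aligner = _build_aligner(scoring)
    alignment = aligner.align(reference.sequence, allele.sequence)[0]
    ref_row, alt_row = str(alignment[0]), str(alignment[1])

    events: list[IndelEvent] = []
    substitutions = 0
    ref_pos = 0  # reference coordinate of the current column
    i = 0
    n = len(ref_row)
    while i < n:
        if ref_row[i] == "-":  # insertion run
            j = i
            while j < n and ref_row[j] == "-":
                j += 1
            inserted = alt_row[i:j]
            events.append(IndelEvent("insertion", ref_pos, j - i, inserted))
            i = j
        elif alt_row[i] == "-":  # deletion run
            j = i
            while j < n and alt_row[j] == "-":
                j += 1
            events.append(IndelEvent("deletion", ref_pos, j - i))
            ref_pos += j - i
            i = j
        else:
            if ref_row[i] != alt_row[i]:
                substitutions += 1
            ref_pos += 1
            i += 1

    events = sorted(
        (_left_align(ev, reference.sequence) for ev in events),
        key=lambda e: (e.ref_position, e.kind),
    )
    return AlleleCall(
        allele_id=allele.id,
        events=events,
        net_change=sum(e.signed_length for e in events),
        substitutions=substitutions,
    )


def _render_allele(reference: str, events: Sequence[IndelEvent]) -> str:
    """Reference rendered with '-' runs for deletions and lowercase insertions."""
    deleted = [False] * len(reference)
    inserts: dict[int, str] = {}
    for ev in events:
        if ev.kind == "deletion":
            for p in range(ev.ref_position, ev.ref_position + ev.length):
                deleted[p] = True
        else:
            inserts[ev.ref_position] = inserts.get(ev.ref_position, "") + ev.inserted_seq
    out: list[str] = []
    for p, base in enumerate(reference):
        if p in inserts:
            out.append(inserts[p].lower())
        out.append("-" if deleted[p] else base)
    if len(reference) in inserts:
        out.append(inserts[len(reference)].lower())
    return "".join(out)


def summarize_alleles(
    calls: Sequence[AlleleCall], reference: SeqRecord | None = None
) -> str:
    """Genotyping-style allele report with ``[xN]`` multiplicities.

    Identical event lists are grouped and their multiplicities summed;
    groups are ordered by (net_change ascending, first event position).
    When ``reference`` is given each group is drawn against the
    reference sequence, deletions as dashes and insertions as lowercase
    letters; otherwise events are listed textually.
    """
    groups: dict[tuple, dict] = {}
    for call in calls:
        key = tuple(
            (e.kind, e.ref_position, e.length, e.inserted_seq) for e in call.events
        )
        g = groups.setdefault(key, {"events": call.events, "n": 0, "ids": []})
        g["n"] += call.multiplicity
        g["ids"].append(call.allele_id)

    def order(item):
        events = item[1]["events"]
        net = sum(e.signed_length for e in events)
        first = events[0].ref_position if events else -1
        return (net, first)

    lines = ["allele\tevents\tnet_change\trendering"]
    for key, g in sorted(groups.items(), key=order):
        events = g["events"]
        net = sum(e.signed_length for e in events)
        desc = (
            ";".join(
                f"{e.kind[:3]}@{e.ref_position}:"
                + (e.inserted_seq if e.kind == "insertion" else str(e.length))
                for e in events
            )
            or "wild-type"
        )
        rendering = (
            _render_allele(reference.sequence, events) if reference is not None else "."
        )
        lines.append(f"{g['ids'][0]}\t{desc}\t{net:+d}\t{rendering} [×{g['n']}]")
    return "\n".join(lines) + "\n"


def t7e1_indel_fraction(
    uncut_intensity: float, cleaved_intensities: Sequence[float]
) -> T7E1Estimate:
    """Estimate mutagenesis frequency from T7E1 gel band intensities.

    ``cleaved_fraction`` is the relative intensity of the cleavage bands.
    Assuming random reannealing of mutant (p) and wild-type strands, the
    heteroduplex fraction is ``1 - (1-p)^2``, inverted here as
    ``p = 1 - sqrt(1 - cleaved_fraction)``.  Both numbers are kept: raw
    band fraction and corrected indel fraction.
    """
    if uncut_intensity < 0 or any(c < 0 for c in cleaved_intensities):
        raise ValueError("band intensities must be >= 0")
    total_cleaved = sum(cleaved_intensities)
    total = uncut_intensity + total_cleaved
    if total == 0:
        raise ValueError("total band intensity is 0")
    cleaved_fraction = total_cleaved / total
    indel_fraction = 1.0 - math.sqrt(max(0.0, 1.0 - cleaved_fraction))
    return T7E1Estimate(
        cleaved_fraction=cleaved_fraction, indel_fraction=indel_fraction
    )
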