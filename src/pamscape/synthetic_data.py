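"""Seeded generators for every input the pipeline consumes.

Random genomes are i.i.d. bases under a configurable composition — the
same null model the closed-form density figures assume — so scanning
them is a direct Monte-Carlo check of those figures.  Exons are
uniformly placed intervals; target sites can be planted at known
coordinates for recall tests; mutant alleles carry known indels for
recovery tests.  Everything is deterministic given its seed.  None of
the generators emulate real genome structure (repeats, isochores, GC
skew, splice structure): passing tests demonstrate correctness of the
computation, not robustness to genomic complexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .density_stats import BaseComposition
from .exon_annotation import ExonInterval
from .sequence_core import IupacPattern, SeqRecord

__all__ = [
    "GenomeSpec",
    "PlantSpec",
    "generate_genome",
    "plant_sites",
    "generate_exons",
    "generate_mutant_alleles",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of a synthetic i.i.d. genome."""

    n_records: int = 1
    record_length: int = 100_000
    composition: BaseComposition = field(default_factory=BaseComposition.uniform)
    seed: int = 0


@dataclass(frozen=True)
class PlantSpec:
    """Where and how to plant concrete PAM matches into a genome.

    ``positions`` lists ``(record_index, offset, strand)`` with ``offset``
    the forward-coordinate start of the PAM window.  ``spacer_fill``
    is ``"random"`` (spacer region resampled N-free) or a fixed string
    of the spacer length.
    """

    pattern: IupacPattern
    positions: tuple[tuple[int, int, str], ...]
    spacer_length: int = 20
    spacer_fill: str = "random"


def generate_genome(spec: GenomeSpec) -> list[SeqRecord]:
    """i.i.d. random records ``syn1..synN`` under the spec's composition."""
    rng = np.random.default_rng(spec.seed)
    comp = spec.composition
    probs = [comp.pA, comp.pC, comp.pG, comp.pT]
    records = []
    for i in range(spec.n_records):
        bases = rng.choice(_BASES, size=spec.record_length, p=probs)
        records.append(SeqRecord(id=f"syn{i + 1}", sequence="".join(bases)))
    return records


def _union_interval(offset: int, k: int, spacer: int, strand: str) -> tuple[int, int]:
    # protospacer sits 3'->5' of the PAM on the targeted strand
    if strand == "+":
        return offset - spacer, offset + k
    return offset, offset + k + spacer


def plant_sites(
    records: Sequence[SeqRecord], plant: PlantSpec, seed: int = 0
) -> list[SeqRecord]:
    """Overwrite chosen windows with concrete matches of the pattern.

    Degenerate pattern positions are sampled uniformly from their
    allowed sets; the spacer region is overwritten too (so the planted
    site is guaranteed scannable, N-free).  Planted protospacer+PAM
    unions may not overlap each other or fall outside their record.
    """
    from .sequence_core import reverse_complement  # local to avoid cycle noise

    rng = np.random.default_rng(seed)
    k = len(plant.pattern)
    spacer_len = plant.spacer_length
    if plant.spacer_fill != "random" and len(plant.spacer_fill) != spacer_len:
        raise ValueError("fixed spacer_fill must have spacer_length bases")

    unions: dict[int, list[tuple[int, int]]] = {}
    for rec_idx, offset, strand in plant.positions:
        if not 0 <= rec_idx < len(records):
            raise ValueError(f"record index {rec_idx} out of range")
        if strand not in "+-":
            raise ValueError(f"bad strand {strand!r}")
        lo, hi = _union_interval(offset, k, spacer_len, strand)
        if lo < 0 or hi > len(records[rec_idx]):
            raise ValueError(
                f"planted site [{lo}, {hi}) lacks spacer room in record {rec_idx}"
            )
        for (plo, phi) in unions.get(rec_idx, []):
            if lo < phi and plo < hi:
                raise ValueError("planted sites overlap")
        unions.setdefault(rec_idx, []).append((lo, hi))

    seqs = [list(r.sequence) for r in records]
    for rec_idx, offset, strand in plant.positions:
        pam = "".join(
            rng.choice(sorted(allowed)) for allowed in plant.pattern.allowed_sets
        )
        if plant.spacer_fill == "random":
            spacer = "".join(rng.choice(_BASES, size=spacer_len))
        else:
            spacer = plant.spacer_fill
        if strand == "+":
            window = spacer + pam
            lo = offset - spacer_len
        else:
            window = reverse_complement(spacer + pam)
            lo = offset
        seqs[rec_idx][lo : lo + len(window)] = list(window)
    return [
        SeqRecord(id=r.id, sequence="".join(s)) for r, s in zip(records, seqs)
    ]


def generate_exons(
    records: Sequence[SeqRecord],
    n_exons: int,
    length_range: tuple[int, int] = (50, 300),
    seed: int = 0,
) -> list[ExonInterval]:
    """Uniformly placed, possibly overlapping exon intervals."""
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid length_range")
    exons = []
    for i in range(n_exons):
        rec = records[int(rng.integers(len(records)))]
        length = int(rng.integers(lo, hi + 1))
        if length > len(rec):
            raise ValueError(f"exon length {length} exceeds record {rec.id}")
        start = int(rng.integers(0, len(rec) - length + 1))
        exons.append(
            ExonInterval(rec.id, start, start + length, name=f"exon{i + 1}", strand=".")
        )
    return exons


def generate_mutant_alleles(
    reference: SeqRecord,
    events_per_allele: Sequence[Sequence[tuple]],
    n_copies: int = 1,
    seed: int = 0,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Build alleles carrying known indels, plus a truth table.

    Each allele is a list of event tuples ``("deletion", pos, length)``
    or ``("insertion", pos, seq)`` with positions on the reference;
    events within one allele may not overlap.  ``n_copies`` replicates
    each allele (distinct ids), emulating repeatedly cloned identical
    alleles.  Returns the allele records and a truth DataFrame with
    columns allele_id, kind, ref_position, length, inserted_seq,
    net_change.
    """
    ref = reference.sequence
    alleles: list[SeqRecord] = []
    truth_rows = []
    for a_idx, events in enumerate(events_per_allele):
        spans = []
        norm = []
        for ev in events:
            kind, pos = ev[0], int(ev[1])
            if kind == "deletion":
                length, ins = int(ev[2]), ""
                span = (pos, pos + length)
                if span[1] > len(ref):
                    raise ValueError("deletion runs past the reference end")
            elif kind == "insertion":
                ins = str(ev[2]).upper()
                length = len(ins)
                span = (pos, pos)
                if pos > len(ref):
                    raise ValueError("insertion position past the reference end")
            else:
                raise ValueError(f"unknown event kind {kind!r}")
            for s in spans:
                if span[0] < s[1] and s[0] < span[1] or span[0] == s[0]:
                    raise ValueError("overlapping events in one allele")
            spans.append(span)
            norm.append((kind, pos, length, ins))
        norm.sort(key=lambda e: e[1])
        # apply right-to-left so earlier positions stay valid
        seq = ref
        for kind, pos, length, ins in reversed(norm):
            if kind == "deletion":
                seq = seq[:pos] + seq[pos + length :]
            else:
                seq = seq[:pos] + ins + seq[pos:]
        net = sum(l if k == "insertion" else -l for k, _, l, _ in norm)
        for copy in range(n_copies):
            allele_id = f"allele{a_idx + 1}_{copy + 1}"
            alleles.append(SeqRecord(id=allele_id, sequence=seq))
            for kind, pos, length, ins in norm:
                truth_rows.append(
                    {
                        "allele_id": allele_id,
                        "kind": kind,
                        "ref_position": pos,
                        "length": length,
                        "inserted_seq": ins,
                        "net_change": net,
                    }
                )
            if not norm:
                truth_rows.append(
                    {
                        "allele_id": allele_id,
                        "kind": "none",
                        "ref_position": -1,
                        "length": 0,
                        "inserted_seq": "",
                        "net_change": 0,
                    }
                )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "allele_id",
            "kind",
            "ref_position",
            "length",
            "inserted_seq",
            "net_change",
        ],
    )
    return alleles, truth
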