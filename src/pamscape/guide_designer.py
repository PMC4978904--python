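"""Oligo design for cloning-free PCR assembly of gRNA transcription templates.

The template for T7 in vitro transcription is assembled by overlap PCR of
two oligos: a forward oligo carrying the T7 promoter, the spacer, and the
first bases of the gRNA scaffold, and a reverse oligo priming the 3' end
of the scaffold.  T7 polymerase initiates efficiently only on G's, so the
spacer's 5' end must supply them — by default missing G's are prepended
(lengthening the spacer), which the round-trip invariant accounts for.

Scaffold sequences differ between Cas systems (Sp vs Sa tracrRNA fusions)
and are deliberately *required* configuration inputs, never hard-coded:
a silently wrong scaffold is worse than a missing one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .pam_scanner import PamSpec, TargetSite, scan_record
from .sequence_core import SeqRecord, reverse_complement

__all__ = [
    "T7_PROMOTER",
    "CasSystemProfile",
    "GuideOligoSet",
    "design_guide",
    "enumerate_guides",
]

#: Minimal T7 RNA polymerase promoter (transcription starts right after it).
T7_PROMOTER = "TAATACGACTCACTATAG"

_MIN_ANNEAL = 15  # bp of scaffold overlap needed for overlap-PCR annealing


@dataclass(frozen=True)
class CasSystemProfile:
    """A Cas nuclease plus the scaffold/promoter context for template PCR."""

    name: str
    pam_class: str
    scaffold_sequence: str
    t7_promoter: str = T7_PROMOTER
    require_5prime_g: int = 2
    five_prime_g_mode: str = "prepend"  # prepend | substitute | reject
    spacer_length: int = 20

    def __post_init__(self):
        if not self.scaffold_sequence:
            raise ValueError("scaffold_sequence must be non-empty")
        if self.five_prime_g_mode not in ("prepend", "substitute", "reject"):
            raise ValueError(f"unknown 5'-G mode {self.five_prime_g_mode!r}")
        if self.require_5prime_g < 0:
            raise ValueError("require_5prime_g must be >= 0")

    def pam_spec(self) -> PamSpec:
        return PamSpec.from_name(self.pam_class, spacer_length=self.spacer_length)


@dataclass(frozen=True)
class GuideOligoSet:
    """The two oligos implementing one guide's transcription template."""

    site: TargetSite
    spacer_used: str
    forward_oligo: str
    reverse_oligo: str
    gc_fraction: float
    warnings: tuple[str, ...] = field(default_factory=tuple)


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def _longest_homopolymer(seq: str) -> int:
    best = run = 0
    prev = ""
    for b in seq:
        run = run + 1 if b == prev else 1
        prev = b
        best = max(best, run)
    return best


def _apply_5prime_g(spacer: str, g_count: int, mode: str) -> tuple[str, list[str]]:
    warnings: list[str] = []
    if g_count == 0 or spacer.startswith("G" * g_count):
        return spacer, warnings
    if mode == "reject":
        raise ValueError(
            f"spacer {spacer!r} does not start with {g_count} G's (mode=reject)"
        )
    if mode == "substitute":
        out = "G" * g_count + spacer[g_count:]
        warnings.append(
            f"substituted first {g_count} nt with G for T7 initiation "
            f"(guide no longer matches genome at its 5' end)"
        )
        return out, warnings
    # prepend: add only as many G's as the 5' end is short of
    missing = 0
    for i in range(g_count):
        if spacer[: g_count - i] == "G" * (g_count - i):
            break
        missing = i + 1
    out = "G" * missing + spacer
    warnings.append(f"prepended {missing} G nt for T7 initiation (+{missing} nt)")
    return out, warnings


def design_guide(
    site: TargetSite,
    profile: CasSystemProfile,
    overlap_fwd: int = 20,
    rev_len: int = 20,
) -> GuideOligoSet:
    """Design the forward/reverse oligo pair for one target site.

    forward = T7 promoter + spacer (5'-G adjusted) + first ``overlap_fwd``
    scaffold bases; reverse = reverse complement of the last ``rev_len``
    scaffold bases.  Warnings flag homopolymer runs >= 5 and GC fraction
    outside [0.3, 0.8].
    """
    if site.pam_class != profile.pam_class:
        raise ValueError(
            f"site PAM class {site.pam_class!r} != profile {profile.pam_class!r}"
        )
    if min(overlap_fwd, rev_len) < _MIN_ANNEAL:
        raise ValueError(f"overlap lengths must be >= {_MIN_ANNEAL} bp")
    scaffold = profile.scaffold_sequence
    if len(scaffold) < max(overlap_fwd, rev_len):
        raise ValueError(
            f"scaffold ({len(scaffold)} bp) shorter than requested overlaps"
        )
    spacer_used, warnings = _apply_5prime_g(
        site.protospacer_seq, profile.require_5prime_g, profile.five_prime_g_mode
    )
    gc = _gc_fraction(spacer_used)
    if not 0.3 <= gc <= 0.8:
        warnings.append(f"spacer GC fraction {gc:.2f} outside [0.30, 0.80]")
    hp = _longest_homopolymer(spacer_used)
    if hp >= 5:
        warnings.append(f"homopolymer run of {hp} nt in spacer")
    return GuideOligoSet(
        site=site,
        spacer_used=spacer_used,
        forward_oligo=profile.t7_promoter + spacer_used + scaffold[:overlap_fwd],
        reverse_oligo=reverse_complement(scaffold[-rev_len:]),
        gc_fraction=gc,
        warnings=tuple(warnings),
    )


def enumerate_guides(
    region: SeqRecord,
    profiles: Sequence[CasSystemProfile],
    overlap_fwd: int = 20,
    rev_len: int = 20,
) -> list[GuideOligoSet]:
    """Design guides for every target site of every profile in a locus.

    Profiles are processed in order and duplicates are not removed, so a
    duplicated profile duplicates its guides.  Bounded to 100 kb — this
    is a locus-level tool, not a genome scanner.
    """
    if len(region) > 100_000:
        raise ValueError("region exceeds the 100 kb locus bound")
    guides: list[GuideOligoSet] = []
    for profile in profiles:
        for site in scan_record(region, profile.pam_spec()):
            guides.append(design_guide(site, profile, overlap_fwd, rev_len))
    return guides
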