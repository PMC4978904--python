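"""Expected vs observed PAM site density under an i.i.d. base model.

For a degenerate motif the per-strand match probability under an
independent-bases composition model is the product over positions of the
summed base probabilities in each allowed set.  Counting both strands,
the expected rate is twice that, and the mean spacing its reciprocal:
under uniform composition the strict SaCas9 PAM ``NNGRRT``
(4·4·1·2·2·1 = 64 of 4096 words) gives 1/64 per strand and one site per
32 bp of random DNA, against 8 bp for SpCas9's ``NGG``.

Edge effects (a length-L record has L-k+1 windows, not L) are ignored —
the spacing is an asymptotic rate with O(k/L) bias — and the z diagnostic
uses a Poisson approximation that neglects overlapping-occurrence
correlation.  Both simplifications are adequate for megabase-scale
scans; see the methods documentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

from .pam_scanner import SiteTable
from .sequence_core import IupacPattern, SeqRecord

__all__ = [
    "BaseComposition",
    "DensityReport",
    "expected_density",
    "empirical_density",
    "compare_densities",
]


@dataclass(frozen=True)
class BaseComposition:
    """Independent per-base probabilities (pA + pC + pG + pT = 1)."""

    pA: float
    pC: float
    pG: float
    pT: float

    def __post_init__(self):
        probs = (self.pA, self.pC, self.pG, self.pT)
        if any(p < 0 for p in probs):
            raise ValueError("base probabilities must be >= 0")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"base probabilities sum to {sum(probs)}, not 1")

    @classmethod
    def uniform(cls) -> "BaseComposition":
        return cls(0.25, 0.25, 0.25, 0.25)

    @classmethod
    def from_records(cls, records: Sequence[SeqRecord]) -> "BaseComposition":
        """Empirical composition of a genome; ``N`` bases are excluded."""
        counts = {b: 0 for b in "ACGT"}
        for rec in records:
            for b in "ACGT":
                counts[b] += rec.sequence.count(b)
        total = sum(counts.values())
        if total == 0:
            raise ValueError("no unambiguous bases to estimate composition from")
        return cls(*(counts[b] / total for b in "ACGT"))

    def prob(self, base: str) -> float:
        return {"A": self.pA, "C": self.pC, "G": self.pG, "T": self.pT}[base]


@dataclass(frozen=True)
class DensityReport:
    """Closed-form and/or observed density figures for one PAM class.

    Spacings are in bp per site (both strands pooled); an impossible
    motif or an empty scan reports ``math.inf`` spacing rather than
    raising.
    """

    pam_class: str
    p_match_per_strand: float | None = None
    expected_rate_both_strands: float | None = None
    expected_spacing: float | None = None
    observed_count: int | None = None
    scanned_bp: int | None = None
    observed_spacing: float | None = None


def expected_density(
    pattern: IupacPattern,
    comp: BaseComposition | None = None,
    pam_class: str | None = None,
) -> DensityReport:
    """Closed-form expected site density of a motif under a composition.

    ``p_match_per_strand`` is the product over pattern positions of the
    allowed-set probability mass; the both-strand rate doubles it.
    """
    comp = comp or BaseComposition.uniform()
    p = 1.0
    for allowed in pattern.allowed_sets:
        p *= sum(comp.prob(b) for b in allowed)
    rate = 2.0 * p
    return DensityReport(
        pam_class=pam_class or pattern.name,
        p_match_per_strand=p,
        expected_rate_both_strands=rate,
        expected_spacing=(1.0 / rate) if rate > 0 else math.inf,
    )


def empirical_density(table: SiteTable, pam_class: str | None = None) -> DensityReport:
    """Observed site density of a finished scan."""
    if table.scanned_bp == 0:
        raise ValueError("scanned_bp is 0; nothing was scanned")
    count = len(table.sites)
    if pam_class is None:
        classes = {s.pam_class for s in table.sites}
        pam_class = classes.pop() if len(classes) == 1 else "mixed"
    return DensityReport(
        pam_class=pam_class,
        observed_count=count,
        scanned_bp=table.scanned_bp,
        observed_spacing=(table.scanned_bp / count) if count else math.inf,
    )


def compare_densities(
    expected: DensityReport, observed: DensityReport, threshold: float = 3.0
) -> tuple[float, bool]:
    """Poisson z-score of an observed count against its closed-form mean.

    Returns ``(z, verdict)`` with ``verdict = |z| <= threshold``.
    Requires both reports to describe the same PAM class.
    """
    if expected.pam_class != observed.pam_class:
        raise ValueError(
            f"class mismatch: {expected.pam_class!r} vs {observed.pam_class!r}"
        )
    if expected.expected_rate_both_strands is None:
        raise ValueError("first argument lacks expected fields")
    if observed.observed_count is None or observed.scanned_bp is None:
        raise ValueError("second argument lacks observed fields")
    mean = expected.expected_rate_both_strands * observed.scanned_bp
    if mean == 0:
        z = math.inf if observed.observed_count else 0.0
    else:
        z = (observed.observed_count - mean) / math.sqrt(mean)
    return z, abs(z) <= threshold


def combine(expected: DensityReport, observed: DensityReport) -> DensityReport:
    """Merge expected-only and observed-only reports for one class."""
    if expected.pam_class != observed.pam_class:
        raise ValueError("class mismatch")
    return replace(
        expected,
        observed_count=observed.observed_count,
        scanned_bp=observed.scanned_bp,
        observed_spacing=observed.observed_spacing,
    )
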