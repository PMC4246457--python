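"""Clonal zygosity classification and cohort summaries.

A diploid clone can carry at most two alleles, so the called-allele
composition of a well maps onto five classes:

* WILDTYPE — only the wildtype allele;
* HETEROZYGOUS — wildtype plus one mutant allele;
* HOMOZYGOUS — a single mutant allele and no wildtype;
* COMPOUND_HETEROZYGOUS — two distinct mutant alleles, no wildtype;
* MIXED — more than two alleles (wildtype counts as one), indicating a well
  founded by several cells or edited after the first division.

Wells failing the coverage gate are NO_CALL.  "Biallelic disrupted" counts
clones with no remaining wildtype allele on either chromosome, i.e.
HOMOZYGOUS + COMPOUND_HETEROZYGOUS.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .variants import AlleleSignature

WILDTYPE = "WILDTYPE"
HETEROZYGOUS = "HETEROZYGOUS"
HOMOZYGOUS = "HOMOZYGOUS"
COMPOUND_HETEROZYGOUS = "COMPOUND_HETEROZYGOUS"
MIXED = "MIXED"
NO_CALL = "NO_CALL"

CLASSES = (WILDTYPE, HETEROZYGOUS, HOMOZYGOUS, COMPOUND_HETEROZYGOUS, MIXED, NO_CALL)

IN_FRAME = "in-frame"
FRAMESHIFT = "frameshift"
NOT_APPLICABLE = "n/a"


def classify_genotype(
    alleles: Sequence[AlleleSignature], minor_evidence: bool = False
) -> str:
    """Map a called-allele composition to its genotype class.

    Total over all compositions: every multiset of called alleles yields
    exactly one class.  ``minor_evidence`` (sub-threshold alleles) never
    changes the class; it is surfaced separately so borderline clones can be
    re-streaked.
    """
    if not alleles:
        return NO_CALL
    has_wt = any(a.is_wildtype for a in alleles)
    if len(alleles) > 2:
        return MIXED
    if len(alleles) == 1:
        return WILDTYPE if has_wt else HOMOZYGOUS
    return HETEROZYGOUS if has_wt else COMPOUND_HETEROZYGOUS


def annotate_frameshift(
    allele: AlleleSignature, coding_frame_offset: int | None
) -> str:
    """Net indel length mod 3 decides frameshift; wildtype and
    substitution-only alleles are in-frame; without frame info, n/a."""
    if coding_frame_offset is None or allele.is_wildtype:
        return NOT_APPLICABLE
    return FRAMESHIFT if allele.net_indel_length % 3 else IN_FRAME


@dataclass(frozen=True)
class GenotypeCall:
    """Zygosity call for one well."""

    well: str  # well name, e.g. "A6"
    genotype_class: str
    alleles: tuple[AlleleSignature, ...]
    minor_allele_evidence: bool = False
    frameshift_status: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.genotype_class not in CLASSES:
            raise ValueError(f"unknown class {self.genotype_class!r}")
        if self.genotype_class == NO_CALL and self.alleles:
            raise ValueError("NO_CALL carries no alleles")


def make_call(
    well: str,
    alleles: Sequence[AlleleSignature],
    minor_evidence: bool = False,
    coding_frame_offset: int | None = None,
) -> GenotypeCall:
    return GenotypeCall(
        well=well,
        genotype_class=classify_genotype(alleles, minor_evidence),
        alleles=tuple(alleles),
        minor_allele_evidence=minor_evidence,
        frameshift_status=tuple(
            annotate_frameshift(a, coding_frame_offset) for a in alleles
        ),
    )


@dataclass(frozen=True)
class CohortSummary:
    """Per-class tallies and the headline screen statistics.

    Two mutation-rate conventions are reported: ``mutated_count`` excludes
    NO_CALL wells from the numerator (denominator ``called_total``), while
    ``mutated_count_including_no_call`` treats unmappable wells as showing
    genetic insult (denominator ``total``) — the convention behind a
    "65 of 67" style headline.
    """

    counts: dict = field(default_factory=dict)
    total: int = 0
    biallelic_disrupted_count: int = 0
    mutated_count: int = 0
    mutated_count_including_no_call: int = 0

    @property
    def called_total(self) -> int:
        return self.total - self.counts.get(NO_CALL, 0)

    @property
    def mutation_rate(self) -> float:
        return self.mutated_count / self.called_total if self.called_total else 0.0

    @property
    def mutation_rate_including_no_call(self) -> float:
        return self.mutated_count_including_no_call / self.total if self.total else 0.0


def summarize_cohort(calls: Sequence[GenotypeCall]) -> CohortSummary:
    """Tally genotype classes across the screen.

    Counts always sum to the input size; biallelic disrupted is
    HOMOZYGOUS + COMPOUND_HETEROZYGOUS; every class except WILDTYPE and
    NO_CALL counts as mutated (MIXED clones show genetic insult).
    """
    counts = Counter(c.genotype_class for c in calls)
    counts = {cls: counts.get(cls, 0) for cls in CLASSES}
    total = len(calls)
    mutated = (
        counts[HETEROZYGOUS]
        + counts[HOMOZYGOUS]
        + counts[COMPOUND_HETEROZYGOUS]
        + counts[MIXED]
    )
    return CohortSummary(
        counts=counts,
        total=total,
        biallelic_disrupted_count=counts[HOMOZYGOUS] + counts[COMPOUND_HETEROZYGOUS],
        mutated_count=mutated,
        mutated_count_including_no_call=mutated + counts[NO_CALL],
    )
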