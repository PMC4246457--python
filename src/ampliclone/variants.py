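"""Allele-signature extraction and sequencing-artifact discrimination.

Each aligned read yields a *signature*: the ordered list of variants whose
left-aligned position falls within a window around the expected cut site
(empty list = wildtype).  Variants outside the window are never
allele-defining — NHEJ repair puts real edits at the cut — and are kept
separately as candidate artifacts.

Two automated filters reproduce what the original screen judged by eye in a
genome browser:

* **Strand bias.**  True alleles are amplified from both template strands
  and appear at roughly equal proportion in plus- and minus-oriented reads;
  platform artifacts are often confined to one read orientation.  An exact
  two-sided binomial test compares a variant's plus fraction against the
  well's overall plus fraction; the variant is called biased only when the
  test rejects (alpha, default 0.01) *and* the plus fraction is extreme
  (>= 0.9 or <= 0.1) — the extremity guard carries most of the specificity.

* **Cross-sample recurrence.**  Artifacts tend to recur at the same
  reference position in many wells; strand-biased out-of-window variants
  seen in >= min_wells wells are blacklisted plate-wide.

Collapsing then merges identical signatures, applies the artifact removals,
and drops sub-threshold alleles (fractions in [minor_floor, min_fraction)
are surfaced as minor-allele evidence of clone mixedness rather than
silently discarded).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy.stats import binomtest

from .align import AlignedRead
from .plate import PlateLayout

DEFAULT_WINDOW = 25
DEFAULT_ALPHA = 0.01
DEFAULT_MIN_ALLELE_FRACTION = 0.20
DEFAULT_MINOR_FLOOR = 0.05
DEFAULT_SUBSTITUTION_MIN_FRACTION = 0.25
DEFAULT_MIN_COVERAGE = 100
DEFAULT_RECURRENCE_MIN_WELLS = 3
EXTREMITY = 0.9


@dataclass(frozen=True)
class Variant:
    """A single left-aligned difference from the reference amplicon."""

    kind: str  # "insertion" | "deletion" | "substitution"
    position: int  # 0-based reference offset (left-aligned)
    length: int
    inserted_sequence: str = ""
    alt_base: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion", "substitution"):
            raise ValueError(f"bad variant kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("variant length must be >= 1")

    @property
    def key(self) -> tuple[int, str]:
        return (self.position, self.kind)

    @property
    def sort_key(self) -> tuple:
        return (self.position, self.kind, self.length, self.inserted_sequence, self.alt_base)

    @property
    def net_length(self) -> int:
        """Signed change in sequence length (+ins, -del, 0 for substitution)."""
        if self.kind == "insertion":
            return self.length
        if self.kind == "deletion":
            return -self.length
        return 0


def variants_from_alignment(aln: AlignedRead, reference: str) -> list[Variant]:
    """Walk the CIGAR and per-M-block comparisons into Variant records."""
    out: list[Variant] = []
    i = 0
    j = aln.reference_start
    for length, op in aln.cigar:
        if op == "M":
            for k in range(length):
                base = aln.sequence[i + k]
                if base != reference[j + k]:
                    out.append(
                        Variant("substitution", j + k, 1, alt_base=base)
                    )
            i += length
            j += length
        elif op == "I":
            out.append(
                Variant("insertion", j, length, inserted_sequence=aln.sequence[i : i + length])
            )
            i += length
        else:  # D
            out.append(Variant("deletion", j, length))
            j += length
    return out


@dataclass(frozen=True)
class ReadSignature:
    """Per-read allele signature: in-window variants plus out-of-window extras."""

    variants: tuple[Variant, ...]
    out_of_window: tuple[Variant, ...]
    orientation: str

    @property
    def is_wildtype(self) -> bool:
        return not self.variants


def extract_allele(
    aln: AlignedRead,
    layout: PlateLayout,
    window: int = DEFAULT_WINDOW,
) -> ReadSignature:
    """Split a read's variants into allele-defining (cut-site window) and
    candidate-artifact (outside) sets."""
    cut = layout.cut_site
    inside: list[Variant] = []
    outside: list[Variant] = []
    for v in variants_from_alignment(aln, layout.reference_amplicon):
        (inside if abs(v.position - cut) <= window else outside).append(v)
    inside.sort(key=lambda v: v.sort_key)
    outside.sort(key=lambda v: v.sort_key)
    return ReadSignature(tuple(inside), tuple(outside), aln.orientation)


def strand_bias_test(
    plus_count: int,
    minus_count: int,
    well_plus_fraction: float,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[float, bool]:
    """Exact two-sided binomial test of a variant's strand balance.

    The variant's plus-read count is tested against the well's overall plus
    fraction.  ``biased`` requires both statistical rejection (p < alpha)
    and an extreme observed fraction (>= 0.9 or <= 0.1), so small counts can
    never be flagged on noise alone.
    """
    n = plus_count + minus_count
    if n < 1:
        raise ValueError("need at least one supporting read")
    p_value = binomtest(plus_count, n, p=well_plus_fraction).pvalue
    frac = plus_count / n
    biased = p_value < alpha and (frac >= EXTREMITY or frac <= 1 - EXTREMITY)
    return float(p_value), biased


@dataclass(frozen=True)
class VariantObservation:
    """Aggregated per-well evidence for one distinct variant."""

    variant: Variant
    in_window: bool
    plus_count: int
    minus_count: int
    p_value: float
    biased: bool

    @property
    def read_count(self) -> int:
        return self.plus_count + self.minus_count


def observe_variants(
    signatures: Sequence[ReadSignature],
    alpha: float = DEFAULT_ALPHA,
) -> list[VariantObservation]:
    """Collapse per-read variants into per-variant strand-support records."""
    if not signatures:
        return []
    plus_total = sum(1 for s in signatures if s.orientation == "plus")
    well_pf = plus_total / len(signatures)
    counts: dict[tuple[Variant, bool], list[int]] = defaultdict(lambda: [0, 0])
    for sig in signatures:
        idx = 0 if sig.orientation == "plus" else 1
        for v in sig.variants:
            counts[(v, True)][idx] += 1
        for v in sig.out_of_window:
            counts[(v, False)][idx] += 1
    out = []
    for (variant, in_window), (p, m) in counts.items():
        p_value, biased = strand_bias_test(p, m, well_pf, alpha)
        out.append(VariantObservation(variant, in_window, p, m, p_value, biased))
    out.sort(key=lambda o: o.variant.sort_key)
    return out


def recurrence_filter(
    observations_by_well: Mapping[str, Sequence[VariantObservation]],
    min_wells: int = DEFAULT_RECURRENCE_MIN_WELLS,
) -> set[tuple[int, str]]:
    """Blacklist (position, kind) pairs of out-of-window, strand-biased
    variants recurring in >= min_wells wells.

    In-window variants supported on both strands can never enter the
    blacklist, so shared true alleles in duplicate clones are safe.
    """
    if len(observations_by_well) < 2:
        raise ValueError("recurrence filtering needs at least two wells")
    tally: Counter = Counter()
    for obs in observations_by_well.values():
        seen = {o.variant.key for o in obs if o.biased and not o.in_window}
        tally.update(seen)
    return {key for key, n in tally.items() if n >= min_wells}


@dataclass(frozen=True)
class AlleleSignature:
    """A collapsed allele: shared variant list with strand-split support."""

    variants: tuple[Variant, ...]
    read_count: int
    plus_count: int
    minus_count: int
    fraction: float

    def __post_init__(self) -> None:
        if self.plus_count + self.minus_count != self.read_count:
            raise ValueError("strand counts must sum to read_count")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction outside [0, 1]")

    @property
    def is_wildtype(self) -> bool:
        return not self.variants

    @property
    def net_indel_length(self) -> int:
        return sum(v.net_length for v in self.variants)


@dataclass(frozen=True)
class ArtifactFlag:
    """Why a variant was removed before allele calling."""

    variant: Variant
    reason: str  # "strand_bias" | "recurrent_across_wells" | "low_support"
    evidence: dict = field(default_factory=dict, compare=False)


@dataclass
class WellAlleleTable:
    """Called alleles for one well after artifact filtering."""

    total_reads: int
    alleles: list[AlleleSignature]
    minor_allele_evidence: bool
    artifact_flags: list[ArtifactFlag]
    dropped_minor_reads: int
    no_call: bool = False

    @property
    def called_reads(self) -> int:
        return sum(a.read_count for a in self.alleles)


def build_allele_table(
    signatures: Sequence[ReadSignature],
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    min_allele_fraction: float = DEFAULT_MIN_ALLELE_FRACTION,
    minor_floor: float = DEFAULT_MINOR_FLOOR,
    alpha: float = DEFAULT_ALPHA,
    substitution_min_fraction: float = DEFAULT_SUBSTITUTION_MIN_FRACTION,
    blacklist: frozenset | set = frozenset(),
) -> WellAlleleTable:
    """Collapse per-read signatures into called alleles for one well.

    Pipeline: remove blacklisted and strand-biased variants from every read,
    collapse identical signatures, demote substitution-only signatures that
    fail the stricter balance/fraction rule to wildtype, then apply the
    allele-fraction threshold.  Read conservation holds: called + dropped
    reads equal the aligned input reads.  Wells below ``min_coverage``
    aligned reads are NO_CALL.
    """
    n = len(signatures)
    if n < min_coverage:
        return WellAlleleTable(
            total_reads=n,
            alleles=[],
            minor_allele_evidence=False,
            artifact_flags=[],
            dropped_minor_reads=0,
            no_call=True,
        )
    flags: list[ArtifactFlag] = []
    removed: set[Variant] = set()
    for obs in observe_variants(signatures, alpha=alpha):
        if not obs.in_window:
            continue
        if obs.variant.key in blacklist:
            removed.add(obs.variant)
            flags.append(
                ArtifactFlag(
                    obs.variant,
                    "recurrent_across_wells",
                    {"plus": obs.plus_count, "minus": obs.minus_count},
                )
            )
        elif obs.biased:
            removed.add(obs.variant)
            flags.append(
                ArtifactFlag(
                    obs.variant,
                    "strand_bias",
                    {
                        "p_value": obs.p_value,
                        "alpha": alpha,
                        "plus": obs.plus_count,
                        "minus": obs.minus_count,
                    },
                )
            )

    groups: dict[tuple[Variant, ...], list[int]] = defaultdict(lambda: [0, 0, 0])
    for sig in signatures:
        key = tuple(v for v in sig.variants if v not in removed)
        rec = groups[key]
        rec[0] += 1
        rec[1 if sig.orientation == "plus" else 2] += 1

    # substitution-only signatures face a stricter gate: single-base errors
    # dominate the platform's noise, so a substitution allele must be both
    # common (>= substitution_min_fraction) and strand-balanced
    for key in [k for k in groups if k and all(v.kind == "substitution" for v in k)]:
        cnt, p, m = groups[key]
        frac = cnt / n
        plus_frac = p / cnt
        extreme = plus_frac >= EXTREMITY or plus_frac <= 1 - EXTREMITY
        if frac < substitution_min_fraction or extreme:
            reason = "strand_bias" if extreme else "low_support"
            for v in key:
                flags.append(
                    ArtifactFlag(
                        v,
                        reason,
                        {"fraction": frac, "plus": p, "minus": m,
                         "min_fraction": substitution_min_fraction},
                    )
                )
            wt = groups[()]
            wt[0] += cnt
            wt[1] += p
            wt[2] += m
            del groups[key]
    if groups.get(()) == [0, 0, 0]:
        del groups[()]

    alleles: list[AlleleSignature] = []
    dropped = 0
    minor = False
    for key, (cnt, p, m) in groups.items():
        frac = cnt / n
        if frac >= min_allele_fraction:
            alleles.append(AlleleSignature(key, cnt, p, m, frac))
        else:
            dropped += cnt
            if frac >= minor_floor:
                minor = True
    alleles.sort(key=lambda a: (-a.read_count, tuple(v.sort_key for v in a.variants)))
    return WellAlleleTable(
        total_reads=n,
        alleles=alleles,
        minor_allele_evidence=minor,
        artifact_flags=flags,
        dropped_minor_reads=dropped,
        no_call=False,
    )


def format_variant(v: Variant, cut_site: int, reference: str | None = None) -> str:
    """Compact cut-site-relative notation, 1-based (no position zero).

    Examples: ``del13@-2``, ``ins3@+1(ACG)``, ``sub@-40(A>G)``.
    """
    rel = v.position - cut_site
    rel1 = rel if rel < 0 else rel + 1
    if v.kind == "deletion":
        return f"del{v.length}@{rel1:+d}"
    if v.kind == "insertion":
        return f"ins{v.length}@{rel1:+d}({v.inserted_sequence})"
    ref_base = reference[v.position] if reference else "N"
    return f"sub@{rel1:+d}({ref_base}>{v.alt_base})"


def format_allele(allele: AlleleSignature, cut_site: int, reference: str | None = None) -> str:
    if allele.is_wildtype:
        return "WT"
    return ";".join(format_variant(v, cut_site, reference) for v in allele.variants)
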