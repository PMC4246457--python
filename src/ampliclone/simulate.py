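"""Synthetic screening runs with full ground truth.

Every upstream stage — demultiplexing, alignment, artifact filtering,
genotyping, QC — is testable against simulated pooled FASTQ whose per-read
origin is known.  Reads are built exactly as the library chemistry dictates:

    [column barcode][fwd primer][allele-modified core][rc(rev primer)][rc(row barcode)]

emitted in plus or minus orientation with probability 1/2 each (single-end
instruments template either strand).  The error model is deliberately
minimal but Ion-Torrent-flavoured:

* per-base substitutions at a configurable rate (default 0.2%);
* homopolymer +/-1 nt indels: a run of length L >= 3 suffers an indel with
  probability ``rate x (L - 2)`` capped at 0.1 — the platform's dominant
  error mode, length-dependent and indel-shaped;
* strand-restricted recurrent artifacts: a fixed substitution or 1 nt indel
  applied only to reads of one orientation at one reference position in a
  chosen set of wells, giving the strand-bias and recurrence filters a
  falsifiable target;
* optional elevated error rate inside the barcode regions.

Per-well depth is lognormal (defaults reproduce a screen whose coverage ran
~300-6600x around a mean of ~2455x) unless a well fixes its depth, which is
how sub-threshold NO_CALL wells are staged.  Identical seed and config give
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._seq import revcomp
from .demux import ReadRecord
from .genotype import (
    COMPOUND_HETEROZYGOUS,
    HETEROZYGOUS,
    HOMOZYGOUS,
    MIXED,
    NO_CALL,
    WILDTYPE,
)
from .example import example_layout
from .plate import PlateLayout, enumerate_wells
from .variants import Variant

_BASES = "ACGT"

DEFAULT_MEAN_DEPTH = 2455.0
DEFAULT_DEPTH_SIGMA = 0.6
DEFAULT_SUBSTITUTION_RATE = 0.002
DEFAULT_HOMOPOLYMER_RATE = 0.005
HOMOPOLYMER_CAP = 0.1
MIN_HOMOPOLYMER = 3
NO_CALL_DEPTH = 30

PAPER_TALLY = {
    HOMOZYGOUS: 10,
    COMPOUND_HETEROZYGOUS: 27,
    HETEROZYGOUS: 4,
    WILDTYPE: 2,
    MIXED: 21,
    NO_CALL: 3,
}


@dataclass(frozen=True)
class AlleleSpec:
    """One true allele: a tuple of variants in reference coordinates."""

    variants: tuple[Variant, ...] = ()
    name: str = "WT"

    @property
    def is_wildtype(self) -> bool:
        return not self.variants

    @staticmethod
    def wildtype() -> "AlleleSpec":
        return AlleleSpec()

    @staticmethod
    def deletion(size: int, position: int) -> "AlleleSpec":
        return AlleleSpec(
            (Variant("deletion", position, size),), name=f"del{size}@{position}"
        )

    @staticmethod
    def insertion(sequence: str, position: int) -> "AlleleSpec":
        return AlleleSpec(
            (Variant("insertion", position, len(sequence), inserted_sequence=sequence),),
            name=f"ins{len(sequence)}@{position}",
        )


@dataclass(frozen=True)
class ArtifactSpec:
    """A strand-restricted recurrent error at a fixed reference position."""

    position: int
    kind: str = "substitution"  # substitution | insertion | deletion
    orientation: str = "minus"
    wells: tuple[str, ...] | None = None  # None = every simulated well
    rate: float = 0.3  # fraction of matching-orientation reads affected
    alt_base: str = "A"


@dataclass(frozen=True)
class WellSimSpec:
    """Allele mixture (fractions summing to 1) and optional fixed depth."""

    alleles: tuple[tuple[AlleleSpec, float], ...]
    depth: int | None = None

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.alleles)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"allele fractions sum to {total}, expected 1")

    def true_class(self, min_coverage: int = 100) -> str:
        if self.depth is not None and self.depth < min_coverage:
            return NO_CALL
        n = len(self.alleles)
        has_wt = any(spec.is_wildtype for spec, _ in self.alleles)
        if n > 2:
            return MIXED
        if n == 1:
            return WILDTYPE if has_wt else HOMOZYGOUS
        return HETEROZYGOUS if has_wt else COMPOUND_HETEROZYGOUS


@dataclass
class SimConfig:
    layout: PlateLayout
    wells: dict  # well name -> WellSimSpec
    mean_depth: float = DEFAULT_MEAN_DEPTH
    depth_sigma: float = DEFAULT_DEPTH_SIGMA
    substitution_error_rate: float = DEFAULT_SUBSTITUTION_RATE
    homopolymer_indel_rate: float = DEFAULT_HOMOPOLYMER_RATE
    barcode_error_rate: float | None = None  # None: same as substitution rate
    artifacts: tuple[ArtifactSpec, ...] = ()

    def __post_init__(self) -> None:
        for rate in (
            self.substitution_error_rate,
            self.homopolymer_indel_rate,
            self.barcode_error_rate or 0.0,
        ):
            if not 0.0 <= rate < 1.0:
                raise ValueError("error rates must lie in [0, 1)")
        known = {w.name for w in enumerate_wells(self.layout)}
        unknown = set(self.wells) - known
        if unknown:
            raise ValueError(f"wells not on the plate: {sorted(unknown)}")


@dataclass(frozen=True)
class ReadTruth:
    well: str
    orientation: str
    allele_index: int
    allele_name: str


@dataclass
class TruthSet:
    """Ground truth for a simulated run (per read and per well)."""

    reads: dict = field(default_factory=dict)  # read id -> ReadTruth
    wells: dict = field(default_factory=dict)  # well name -> WellSimSpec
    classes: dict = field(default_factory=dict)  # well name -> true class
    depths: dict = field(default_factory=dict)  # well name -> drawn depth


def apply_allele(layout: PlateLayout, spec: AlleleSpec) -> str:
    """Reference amplicon with the allele's variants applied.

    Variants must lie strictly inside the primer-free interior so the PCR
    handles stay intact.
    """
    lo, hi = layout.interior_start, layout.interior_end
    seq = layout.reference_amplicon
    for v in sorted(spec.variants, key=lambda v: -v.position):
        end = v.position + (v.length if v.kind == "deletion" else 0)
        if not (lo <= v.position and end <= hi):
            raise ValueError(f"variant {v} outside the amplicon interior")
        if v.kind == "deletion":
            seq = seq[: v.position] + seq[v.position + v.length :]
        elif v.kind == "insertion":
            seq = seq[: v.position] + v.inserted_sequence + seq[v.position :]
        else:
            seq = seq[: v.position] + v.alt_base + seq[v.position + 1 :]
    return seq


def _apply_point_edit(seq: str, pos: int, kind: str, alt: str) -> str:
    if pos >= len(seq):
        return seq
    if kind == "substitution":
        base = alt if seq[pos] != alt else ("C" if alt != "C" else "G")
        return seq[:pos] + base + seq[pos + 1 :]
    if kind == "insertion":
        return seq[:pos] + alt + seq[pos:]
    return seq[:pos] + seq[pos + 1 :]  # deletion


def _homopolymer_runs(seq: str, min_len: int = MIN_HOMOPOLYMER):
    runs = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            if i - start >= min_len:
                runs.append((start, i - start))
            start = i
    return runs


def _apply_errors(
    seq: str,
    rng: np.random.Generator,
    sub_rate: float,
    hp_rate: float,
    bc_rate: float | None,
    bc_left: int,
    bc_right: int,
) -> str:
    # homopolymer +/-1 indels, applied right-to-left so positions stay valid
    if hp_rate > 0:
        edits = []
        for start, length in _homopolymer_runs(seq):
            p = min(hp_rate * (length - 2), HOMOPOLYMER_CAP)
            if rng.random() < p:
                edits.append((start, rng.random() < 0.5))
        for start, is_insertion in reversed(edits):
            if is_insertion:
                seq = seq[:start] + seq[start] + seq[start:]
            else:
                seq = seq[:start] + seq[start + 1 :]
    # substitutions (optionally elevated in the barcode regions)
    n = len(seq)
    draws = rng.random(n)
    if bc_rate is None:
        hits = np.nonzero(draws < sub_rate)[0]
    else:
        rates = np.full(n, sub_rate)
        rates[:bc_left] = bc_rate
        if bc_right:
            rates[n - bc_right :] = bc_rate
        hits = np.nonzero(draws < rates)[0]
    if hits.size:
        chars = list(seq)
        for pos in hits:
            old = chars[pos]
            choices = [b for b in _BASES if b != old]
            chars[pos] = choices[rng.integers(0, 3)]
        seq = "".join(chars)
    return seq


def simulate_run(
    config: SimConfig, seed: int = 0
) -> tuple[list[ReadRecord], TruthSet]:
    """Emit pooled reads for every configured well, plus ground truth.

    Deterministic for a given (config, seed); the emitted read count equals
    the sum of drawn per-well depths.
    """
    rng = np.random.default_rng(seed)
    layout = config.layout
    col_by_id = {b.id: b for b in layout.column_barcodes}
    row_by_id = {b.id: b for b in layout.row_barcodes}
    mu = math.log(config.mean_depth) - config.depth_sigma**2 / 2

    reads: list[ReadRecord] = []
    truth = TruthSet()
    for well in enumerate_wells(layout):
        spec = config.wells.get(well.name)
        if spec is None:
            continue
        bc_f = col_by_id[well.column_barcode_id].sequence
        bc_r = row_by_id[well.row_barcode_id].sequence
        suffix = revcomp(bc_r)
        cores = [apply_allele(layout, a) for a, _ in spec.alleles]
        fractions = np.array([f for _, f in spec.alleles])
        fractions = fractions / fractions.sum()
        depth = (
            spec.depth
            if spec.depth is not None
            else max(1, int(round(rng.lognormal(mu, config.depth_sigma))))
        )
        truth.wells[well.name] = spec
        truth.classes[well.name] = spec.true_class()
        truth.depths[well.name] = depth
        artifacts = [
            a
            for a in config.artifacts
            if a.wells is None or well.name in a.wells
        ]
        for r in range(depth):
            idx = int(rng.choice(len(cores), p=fractions))
            orientation = "plus" if rng.random() < 0.5 else "minus"
            seq = bc_f + cores[idx] + suffix
            for art in artifacts:
                if art.orientation == orientation and rng.random() < art.rate:
                    seq = _apply_point_edit(
                        seq, len(bc_f) + art.position, art.kind, art.alt_base
                    )
            seq = _apply_errors(
                seq,
                rng,
                config.substitution_error_rate,
                config.homopolymer_indel_rate,
                config.barcode_error_rate,
                len(bc_f),
                len(bc_r),
            )
            if orientation == "minus":
                seq = revcomp(seq)
            read_id = f"sim:{well.name}:{r}"
            reads.append(ReadRecord(read_id, seq, "I" * len(seq)))
            truth.reads[read_id] = ReadTruth(
                well.name, orientation, idx, spec.alleles[idx][0].name
            )
    return reads, truth


def _draw_mutant(
    rng: np.random.Generator, layout: PlateLayout, used: set
) -> AlleleSpec:
    """A random indel allele, sizes 1-30 nt, centred on the cut site,
    distinct (kind, size) within a well."""
    cut = layout.cut_site
    while True:
        size = int(rng.integers(1, 31))
        kind = "deletion" if rng.random() < 0.75 else "insertion"
        if (kind, size) in used:
            continue
        used.add((kind, size))
        if kind == "deletion":
            return AlleleSpec.deletion(size, cut - size // 2)
        ins = "".join(_BASES[i] for i in rng.integers(0, 4, size=size))
        return AlleleSpec.insertion(ins, cut)


def default_artifacts(layout: PlateLayout) -> tuple[ArtifactSpec, ...]:
    """Two plate-wide strand-restricted artifacts outside the cut window:
    a minus-only substitution upstream, a plus-only 1 nt deletion downstream."""
    return (
        ArtifactSpec(position=30, kind="substitution", orientation="minus", rate=0.3),
        ArtifactSpec(position=165, kind="deletion", orientation="plus", rate=0.3),
    )


def make_paper_cohort(
    seed: int = 0,
    layout: PlateLayout | None = None,
    depth: int | None = None,
    mean_depth: float = DEFAULT_MEAN_DEPTH,
    with_artifacts: bool = True,
) -> SimConfig:
    """A 67-well screen whose true classes follow the reference tally:
    10 homozygous, 27 compound heterozygous, 4 heterozygous, 2 wildtype,
    21 mixed, and 3 wells at sub-threshold depth (NO_CALL).

    ``depth`` fixes per-well depth for every callable well (NO_CALL wells
    are always staged at depth 30); None draws lognormal depths.
    """
    layout = layout or example_layout()
    rng = np.random.default_rng(seed)
    well_names = [w.name for w in enumerate_wells(layout)][: sum(PAPER_TALLY.values())]
    classes = [cls for cls, n in PAPER_TALLY.items() for _ in range(n)]
    rng.shuffle(classes)

    wt = AlleleSpec.wildtype()
    wells: dict[str, WellSimSpec] = {}
    for name, cls in zip(well_names, classes):
        used: set = set()
        if cls == WILDTYPE:
            alleles = ((wt, 1.0),)
        elif cls == NO_CALL:
            alleles = ((wt, 1.0),)
        elif cls == HOMOZYGOUS:
            alleles = ((_draw_mutant(rng, layout, used), 1.0),)
        elif cls == HETEROZYGOUS:
            alleles = ((wt, 0.5), (_draw_mutant(rng, layout, used), 0.5))
        elif cls == COMPOUND_HETEROZYGOUS:
            alleles = (
                (_draw_mutant(rng, layout, used), 0.5),
                (_draw_mutant(rng, layout, used), 0.5),
            )
        else:  # MIXED: three alleles, half the wells keep a wildtype one
            first = wt if rng.random() < 0.5 else _draw_mutant(rng, layout, used)
            alleles = (
                (first, 0.34),
                (_draw_mutant(rng, layout, used), 0.33),
                (_draw_mutant(rng, layout, used), 0.33),
            )
        well_depth = NO_CALL_DEPTH if cls == NO_CALL else depth
        wells[name] = WellSimSpec(alleles=alleles, depth=well_depth)

    return SimConfig(
        layout=layout,
        wells=wells,
        mean_depth=mean_depth,
        artifacts=default_artifacts(layout) if with_artifacts else (),
    )


def clone_a6_config(
    layout: PlateLayout | None = None,
    depth: int = 400,
    well: str = "A6",
) -> SimConfig:
    """The worked example: a compound heterozygote carrying a 1 bp and a
    13 bp deletion at equal proportion, balanced across strands."""
    layout = layout or example_layout()
    cut = layout.cut_site
    spec = WellSimSpec(
        alleles=(
            (AlleleSpec.deletion(1, cut), 0.5),
            (AlleleSpec.deletion(13, cut - 6), 0.5),
        ),
        depth=depth,
    )
    return SimConfig(layout=layout, wells={well: spec})
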