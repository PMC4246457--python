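"""Combinatorial barcode demultiplexing of pooled single-end amplicon reads.

Library structure (plus orientation):

    [column barcode][fwd primer][amplicon core][rc(rev primer)][rc(row barcode)]

Ion-Torrent-style single-end reads may enter from either adaptor, so a read
is tried in both orientations: the orientation in which the column barcode
leads is labelled "plus", the reverse complement "minus".  This per-read
orientation is the only strand signal single-end amplicon data carries and is
consumed downstream by the strand-bias artifact filter.

Matching is anchored: the leading barcode is read off the 5' end, the
trailing (reverse-complemented) barcode off the 3' end with a small
adaptor-trimming slop.  Ties between distinct barcodes at the minimal
mismatch count are never broken arbitrarily — the read goes unassigned,
because a silently misassigned read corrupts a genotype.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._seq import hamming, revcomp
from .plate import Barcode, PlateLayout, WellIdentity, enumerate_wells

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read (Sanger phred+33 qualities, optional)."""

    id: str
    sequence: str
    qualities: str | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality/sequence length mismatch")


@dataclass
class DemuxParams:
    max_mismatch_per_barcode: int = 1
    require_both_barcodes: bool = True
    min_read_length: int = 50
    end_slop: int = 2  # tolerated 3'-adaptor-trimming slop (bases)

    def __post_init__(self) -> None:
        if self.max_mismatch_per_barcode < 0:
            raise ValueError("max_mismatch_per_barcode must be >= 0")


@dataclass(frozen=True)
class WellAssignment:
    """Outcome of demultiplexing one read."""

    read_id: str
    well: WellIdentity | None
    orientation: str | None  # "plus" | "minus" when assigned
    fwd_mismatches: int | None
    rev_mismatches: int | None
    trimmed_sequence: str
    trimmed_qualities: str | None = None
    reason: str | None = None  # set when well is None

    @property
    def assigned(self) -> bool:
        return self.well is not None


def match_barcode(
    prefix: str, candidates: Sequence[Barcode], max_mismatch: int
) -> tuple[Barcode | None, int | None]:
    """Match a read prefix against anchored barcode candidates.

    Returns the unique candidate at minimal Hamming distance <= max_mismatch,
    or (None, None) when nothing matches or two distinct candidates tie at
    the minimal distance.  Candidates longer than the prefix are skipped.
    """
    if not candidates:
        raise ValueError("no barcode candidates")
    best: Barcode | None = None
    best_d: int | None = None
    tie = False
    for bc in candidates:
        k = len(bc.sequence)
        if len(prefix) < k:
            continue
        d = hamming(prefix[:k], bc.sequence)
        if best_d is None or d < best_d:
            best, best_d, tie = bc, d, False
        elif d == best_d and bc.sequence != best.sequence:
            tie = True
    if best is None or tie or best_d > max_mismatch:
        return None, None
    return best, best_d


def match_trailing_barcode(
    seq: str, candidates: Sequence[Barcode], max_mismatch: int, slop: int
) -> tuple[Barcode | None, int | None, int | None]:
    """Match the reverse-complemented barcode anchored at the 3' end.

    Tries offsets 0..slop from the read terminus; for equal mismatch counts
    the smallest offset wins.  Returns (barcode, mismatches, offset) or
    (None, None, None) on a miss or an inter-barcode tie.
    """
    best: Barcode | None = None
    best_d: int | None = None
    best_s: int | None = None
    tie = False
    for bc in candidates:
        target = revcomp(bc.sequence)
        k = len(target)
        for s in range(slop + 1):
            end = len(seq) - s
            start = end - k
            if start < 0:
                continue
            d = hamming(seq[start:end], target)
            if best_d is None or d < best_d:
                best, best_d, best_s, tie = bc, d, s, False
            elif d == best_d and bc.sequence != best.sequence:
                tie = True
    if best is None or tie or best_d > max_mismatch:
        return None, None, None
    return best, best_d, best_s


def _unassigned(read: ReadRecord, reason: str) -> WellAssignment:
    return WellAssignment(
        read_id=read.id,
        well=None,
        orientation=None,
        fwd_mismatches=None,
        rev_mismatches=None,
        trimmed_sequence="",
        trimmed_qualities=None,
        reason=reason,
    )


def assign_read(
    read: ReadRecord, layout: PlateLayout, params: DemuxParams
) -> WellAssignment:
    """Assign a read to a well via its (column, row) barcode pair.

    Plus orientation is tried first (column barcode leading), then the
    reverse complement.  The trimmed sequence excludes both barcodes and both
    target-primer regions, leaving only amplicon-core sequence for alignment.
    """
    if len(read.sequence) < params.min_read_length:
        return _unassigned(read, "too_short")

    wells = {
        (w.column_barcode_id, w.row_barcode_id): w for w in enumerate_wells(layout)
    }
    mm = params.max_mismatch_per_barcode
    saw_partial = False
    for orientation in ("plus", "minus"):
        if orientation == "plus":
            seq, quals = read.sequence, read.qualities
        else:
            seq = revcomp(read.sequence)
            quals = read.qualities[::-1] if read.qualities is not None else None
        col, fd = match_barcode(seq, layout.column_barcodes, mm)
        row, rd, slop = match_trailing_barcode(
            seq, layout.row_barcodes, mm, params.end_slop
        )
        if col is not None and row is not None:
            start = len(col.sequence) + len(layout.fwd_target_primer)
            end = len(seq) - slop - len(row.sequence) - len(layout.rev_target_primer)
            if end <= start:
                return _unassigned(read, "too_short")
            return WellAssignment(
                read_id=read.id,
                well=wells[(col.id, row.id)],
                orientation=orientation,
                fwd_mismatches=fd,
                rev_mismatches=rd,
                trimmed_sequence=seq[start:end],
                trimmed_qualities=quals[start:end] if quals is not None else None,
                reason=None,
            )
        if (col is not None) != (row is not None):
            saw_partial = True
            if not params.require_both_barcodes:
                # single-barcode assignment is ambiguous across a full
                # row/column, so it still cannot name a well; recorded as
                # partial either way
                pass
    return _unassigned(read, "partial" if saw_partial else "no_barcode")


@dataclass
class DemuxResult:
    """Per-well read bins plus unassigned pile and bookkeeping tallies."""

    assignments: dict[str, list[WellAssignment]]  # well name -> assigned reads
    unassigned: list[WellAssignment]
    counts: Counter = field(default_factory=Counter)  # well name -> reads
    unassigned_reasons: Counter = field(default_factory=Counter)
    total_reads: int = 0

    @property
    def assigned_reads(self) -> int:
        return sum(self.counts.values())

    def summary_rows(self) -> list[dict]:
        total = max(self.total_reads, 1)
        rows = [
            {"well": name, "reads": self.counts.get(name, 0),
             "fraction": self.counts.get(name, 0) / total}
            for name in self.assignments
        ]
        rows.append(
            {"well": UNASSIGNED, "reads": len(self.unassigned),
             "fraction": len(self.unassigned) / total}
        )
        return rows


def demultiplex(
    reads: Iterable[ReadRecord],
    layout: PlateLayout,
    params: DemuxParams | None = None,
    out_dir: str | os.PathLike | None = None,
    run_name: str = "run",
) -> DemuxResult:
    """Bin every read into exactly one well (or the unassigned pile).

    When ``out_dir`` is given, raw (untrimmed) reads are also written to one
    FASTQ per well named ``<run>_<row><column>.fastq`` plus an unassigned
    FASTQ, mirroring the one-file-per-clone convention of the original
    screen.  Conservation holds by construction: bin sizes sum to the input
    read count.
    """
    params = params or DemuxParams()
    result = DemuxResult(
        assignments={w.name: [] for w in enumerate_wells(layout)},
        unassigned=[],
    )
    handles: dict[str, object] = {}

    def _handle(name: str):
        if out_dir is None:
            return None
        if name not in handles:
            os.makedirs(out_dir, exist_ok=True)
            handles[name] = open(
                os.path.join(out_dir, f"{run_name}_{name}.fastq"), "w"
            )
        return handles[name]

    try:
        for read in reads:
            result.total_reads += 1
            assignment = assign_read(read, layout, params)
            if assignment.assigned:
                name = assignment.well.name
                result.assignments[name].append(assignment)
                result.counts[name] += 1
            else:
                name = UNASSIGNED
                result.unassigned.append(assignment)
                result.unassigned_reasons[assignment.reason] += 1
            fh = _handle(name)
            if fh is not None:
                quals = read.qualities or "I" * len(read.sequence)
                fh.write(f"@{read.id}\n{read.sequence}\n+\n{quals}\n")
    finally:
        for fh in handles.values():
            fh.close()
    return result
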