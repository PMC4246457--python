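"""Affine-gap glocal alignment of trimmed amplicon reads.

CRISPR clones carry deletions of up to tens of bases at the cut site.  A
standard aligner with steep gap-extension penalties shreds such deletions
into soft-clips or mismatch runs; this aligner therefore uses a relaxed
affine model in which a gap of length k costs ``gap_open + k * gap_extend``
(default 5 + k, the read-gap relaxation the original screen applied to its
mapper), so a 13 bp deletion costs 18 instead of being split.

Mode is glocal: the read must align end-to-end (after barcode/primer
trimming it is wholly amplicon-derived) while reference overhangs are free.
The dynamic program is a Gotoh three-state recurrence over

    H[i,j] = best score with read[:i] aligned ending at ref position j
    D[i,j] = ... ending in a deletion (reference consumed, read gapped)
    I[i,j] = ... ending in an insertion (read consumed, reference gapped)

with H[0,j] = 0 (free reference prefix) and the final score the maximum of
the last row (free reference suffix).  Traceback prefers matches over gaps
and gap extension over opening, and emitted indels are then left-normalized
(shifted maximally left within repeats) so equivalent alignments produce
identical CIGARs and allele signatures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pysam
from numba import njit

from ._seq import encode
from .plate import PlateLayout

_NEG = np.int64(-(1 << 40))

# H-state provenance codes
_FROM_M, _FROM_D, _FROM_I = 0, 1, 2

CIGAR_OPS = {"M": 0, "I": 1, "D": 2}


@dataclass(frozen=True)
class ScoringScheme:
    """Integer scoring for the glocal affine-gap model.

    A length-k gap costs ``gap_open + k * gap_extend``.  ``min_score_fraction``
    sets the alignability floor: alignments scoring below
    ``min_score_fraction * match_score * read_length`` are rejected.
    """

    match_score: int = 2
    mismatch_penalty: int = 4
    gap_open_penalty: int = 5
    gap_extend_penalty: int = 1
    min_score_fraction: float = 0.4

    def __post_init__(self) -> None:
        if min(self.mismatch_penalty, self.gap_open_penalty, self.gap_extend_penalty) < 0:
            raise ValueError("penalties must be >= 0")
        if self.gap_extend_penalty > self.gap_open_penalty:
            raise ValueError("gap_extend_penalty must be <= gap_open_penalty")


@dataclass(frozen=True)
class AlignedRead:
    """A glocal alignment of one trimmed read against the amplicon."""

    read_id: str
    sequence: str  # trimmed read, in reference (plus) frame
    reference_start: int  # 0-based
    cigar: tuple[tuple[int, str], ...]  # (length, op) with op in {M, I, D}
    orientation: str  # "plus" | "minus"
    score: int

    @property
    def read_span(self) -> int:
        return sum(n for n, op in self.cigar if op in "MI")

    @property
    def reference_span(self) -> int:
        return sum(n for n, op in self.cigar if op in "MD")

    @property
    def reference_end(self) -> int:
        return self.reference_start + self.reference_span


@njit(cache=True, nogil=True)
def _fill(read, ref, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = read.shape[0]
    m = ref.shape[0]
    H = np.full((n + 1, m + 1), _NEG, np.int64)
    D = np.full((n + 1, m + 1), _NEG, np.int64)
    I = np.full((n + 1, m + 1), _NEG, np.int64)
    ptr_h = np.zeros((n + 1, m + 1), np.uint8)  # which state attained H
    ptr_d = np.zeros((n + 1, m + 1), np.uint8)  # 1 = extended, 0 = opened
    ptr_i = np.zeros((n + 1, m + 1), np.uint8)
    for j in range(m + 1):
        H[0, j] = 0
    for i in range(1, n + 1):
        I[i, 0] = -(gap_open + i * gap_extend)
        H[i, 0] = I[i, 0]
        ptr_h[i, 0] = _FROM_I
        if i > 1:
            ptr_i[i, 0] = 1
        a = read[i - 1]
        for j in range(1, m + 1):
            s = match if (a == ref[j - 1] and a < 4) else -mismatch
            m_score = H[i - 1, j - 1] + s
            d_open = H[i, j - 1] - gap_open - gap_extend
            d_ext = D[i, j - 1] - gap_extend
            if d_ext >= d_open:  # tie -> extend (fewer gap openings)
                D[i, j] = d_ext
                ptr_d[i, j] = 1
            else:
                D[i, j] = d_open
            i_open = H[i - 1, j] - gap_open - gap_extend
            i_ext = I[i - 1, j] - gap_extend
            if i_ext >= i_open:
                I[i, j] = i_ext
                ptr_i[i, j] = 1
            else:
                I[i, j] = i_open
            best = m_score
            state = _FROM_M
            if D[i, j] > best:
                best = D[i, j]
                state = _FROM_D
            if I[i, j] > best:
                best = I[i, j]
                state = _FROM_I
            H[i, j] = best
            ptr_h[i, j] = state
    end_j = 0
    best = H[n, 0]
    for j in range(1, m + 1):
        if H[n, j] > best:  # strict: leftmost end on ties
            best = H[n, j]
            end_j = j
    return best, end_j, ptr_h, ptr_d, ptr_i


def _traceback(ptr_h, ptr_d, ptr_i, n: int, end_j: int):
    """Recover (ref_start, ops) from the pointer matrices."""
    ops: list[str] = []
    i, j = n, end_j
    state = ptr_h[i, j]
    while i > 0:
        if state == _FROM_M:
            ops.append("M")
            i -= 1
            j -= 1
            state = ptr_h[i, j]
        elif state == _FROM_D:
            ops.append("D")
            extended = ptr_d[i, j] == 1
            j -= 1
            state = _FROM_D if extended else ptr_h[i, j]
        else:  # insertion
            ops.append("I")
            extended = ptr_i[i, j] == 1
            i -= 1
            state = _FROM_I if extended else ptr_h[i, j]
    ops.reverse()
    return j, ops


def _run_length(ops: Sequence[str]) -> list[tuple[int, str]]:
    out: list[tuple[int, str]] = []
    for op in ops:
        if out and out[-1][1] == op:
            out[-1] = (out[-1][0] + 1, op)
        else:
            out.append((1, op))
    return out


def _left_normalize(
    ref: str, ref_start: int, read: str, cigar: list[tuple[int, str]]
) -> tuple[int, tuple[tuple[int, str], ...]]:
    """Left-align indels within repeats and rebuild the CIGAR.

    Each indel is shifted maximally left while the flanking reference (for
    deletions) or the rotated inserted sequence (for insertions) repeats,
    without crossing the previous indel or the alignment start.  This makes
    the representation canonical: two reads carrying the same physical indel
    in a homopolymer collapse to identical signatures.
    """
    # collect indels with absolute coordinates
    indels: list[list] = []  # [pos, kind, length, inserted_seq]
    i = 0
    j = ref_start
    for length, op in cigar:
        if op == "M":
            i += length
            j += length
        elif op == "D":
            indels.append([j, "D", length, ""])
            j += length
        else:
            indels.append([j, "I", length, read[i : i + length]])
            i += length
    read_len = i

    floor_d = ref_start + 1  # keep >=1 leading M: no leading deletion
    floor_i = ref_start
    for idx, rec in enumerate(indels):
        pos, kind, length, ins = rec
        if kind == "D":
            while pos > floor_d and ref[pos - 1] == ref[pos + length - 1]:
                pos -= 1
            rec[0] = pos
            floor_d = pos + length + 1
            floor_i = pos + length
        else:
            while pos > floor_i and ref[pos - 1] == ins[-1]:
                ins = ref[pos - 1] + ins[:-1]
                pos -= 1
            rec[0], rec[3] = pos, ins
            floor_d = pos + 1
            floor_i = pos

    ops: list[tuple[int, str]] = []
    rp = 0
    jp = ref_start
    for pos, kind, length, ins in indels:
        gap = pos - jp
        if gap:
            ops.append((gap, "M"))
            rp += gap
            jp += gap
        ops.append((length, kind))
        if kind == "D":
            jp += length
        else:
            rp += length
    if read_len - rp:
        ops.append((read_len - rp, "M"))
    new_start = ref_start
    # merge adjacent same-op blocks produced by zero-length M gaps
    merged: list[tuple[int, str]] = []
    for length, op in ops:
        if merged and merged[-1][1] == op:
            merged[-1] = (merged[-1][0] + length, op)
        else:
            merged.append((length, op))
    return new_start, tuple(merged)


def align_read(
    trimmed: str,
    reference: str,
    scoring: ScoringScheme | None = None,
    read_id: str = "",
    orientation: str = "plus",
) -> AlignedRead | None:
    """Align one trimmed read glocally against the reference amplicon.

    Returns None (unalignable) when the optimal score falls below the
    configured floor.  Emitted CIGARs satisfy the conservation invariants
    (M+I lengths sum to the read length, M+D to the reference span) and
    indels are left-normalized.
    """
    if not trimmed or not reference:
        raise ValueError("empty sequence")
    scoring = scoring or ScoringScheme()
    score, end_j, ptr_h, ptr_d, ptr_i = _fill(
        encode(trimmed),
        encode(reference),
        scoring.match_score,
        scoring.mismatch_penalty,
        scoring.gap_open_penalty,
        scoring.gap_extend_penalty,
    )
    score = int(score)
    if score < scoring.min_score_fraction * scoring.match_score * len(trimmed):
        return None
    ref_start, ops = _traceback(ptr_h, ptr_d, ptr_i, len(trimmed), int(end_j))
    ref_start, cigar = _left_normalize(reference, ref_start, trimmed, _run_length(ops))
    return AlignedRead(
        read_id=read_id,
        sequence=trimmed,
        reference_start=ref_start,
        cigar=cigar,
        orientation=orientation,
        score=score,
    )


def sam_header(layout: PlateLayout, reference_name: str = "amplicon") -> pysam.AlignmentHeader:
    from . import __version__

    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": reference_name, "LN": len(layout.reference_amplicon)}],
            "PG": [{"ID": "ampliclone", "PN": "ampliclone", "VN": __version__}],
        }
    )


def write_sam(
    alignments: Sequence[AlignedRead],
    layout: PlateLayout,
    path,
    reference_name: str = "amplicon",
) -> None:
    """Write alignments as SAM against the single amplicon reference.

    Minus-orientation reads carry the reverse-strand flag; SEQ is stored in
    reference frame (i.e. reverse-complemented relative to the instrument
    read), per SAM convention.
    """
    header = sam_header(layout, reference_name)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            seg = pysam.AlignedSegment(header)
            seg.query_name = aln.read_id or "read"
            seg.query_sequence = aln.sequence
            seg.flag = 16 if aln.orientation == "minus" else 0
            seg.reference_id = 0
            seg.reference_start = aln.reference_start
            seg.mapping_quality = 60
            seg.cigartuples = [(CIGAR_OPS[op], n) for n, op in aln.cigar]
            out.write(seg)


def write_reference_fasta(layout: PlateLayout, path, reference_name: str = "amplicon") -> None:
    """Write the amplicon reference as FASTA (for IGV alongside the SAM)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    record = SeqRecord(Seq(layout.reference_amplicon), id=reference_name, description="")
    SeqIO.write([record], str(path), "fasta")
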