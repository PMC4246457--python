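"""Row/column barcoded plate geometry for pooled amplicon screens.

A 96-well screen is indexed combinatorially: each well's amplicon carries a
column barcode on the forward fusion primer and a row barcode on the reverse
fusion primer, so ``c + r`` oligos uniquely label ``c x r`` clones (12 + 8
primers for a full plate of 96).  The layout also records the target-specific
primer sequences, the reference amplicon they define (typically ~200 bp, the
guide site flanked by ~100 bp either side) and the expected Cas9 cut site.

Coordinates are 0-based half-open internally; user-facing reports and the
layout config file use 1-based positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import edlib

from ._seq import hamming, is_dna, revcomp

ROW_LABELS = "ABCDEFGH"
MAX_COLUMNS = 12
MAX_ROWS = 8

DEFAULT_MIN_BARCODE_DISTANCE = 3


@dataclass(frozen=True)
class Barcode:
    """A short in-line sample barcode (~10 nt) on a fusion primer.

    role is "column" for forward-primer barcodes, "row" for reverse-primer
    barcodes.
    """

    id: str
    sequence: str
    role: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("barcode id must be non-empty")
        if not is_dna(self.sequence):
            raise ValueError(
                f"barcode {self.id!r}: sequence must be non-empty A/C/G/T"
            )
        if self.role not in ("column", "row"):
            raise ValueError(f"barcode {self.id!r}: role must be column|row")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class WellIdentity:
    """One well of the plate, identified by its (column, row) barcode pair."""

    row_label: str
    column_label: int
    column_barcode_id: str
    row_barcode_id: str

    @property
    def name(self) -> str:
        return f"{self.row_label}{self.column_label}"


def barcode_distance(a: str, b: str) -> int:
    """Hamming distance for equal lengths, edit distance otherwise."""
    if len(a) == len(b):
        return hamming(a, b)
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass(frozen=True)
class ValidationReport:
    """Result of pairwise-distance screening of a barcode set."""

    min_distance: int | None  # None for a singleton set (undefined)
    flagged_pairs: tuple[tuple[str, str, int], ...]
    threshold: int

    @property
    def passed(self) -> bool:
        return not self.flagged_pairs


def validate_barcode_set(
    barcodes: Sequence[Barcode], min_distance: int = DEFAULT_MIN_BARCODE_DISTANCE
) -> ValidationReport:
    """Screen a barcode set for pairs closer than ``min_distance``.

    Distance is Hamming over equal-length pairs and edit distance when
    lengths differ.  A singleton set trivially passes with an undefined
    minimum distance.
    """
    if not barcodes:
        raise ValueError("barcode set is empty")
    flagged = []
    min_d: int | None = None
    for a, b in combinations(barcodes, 2):
        d = barcode_distance(a.sequence, b.sequence)
        if min_d is None or d < min_d:
            min_d = d
        if d < min_distance:
            flagged.append((a.id, b.id, d))
    return ValidationReport(
        min_distance=min_d, flagged_pairs=tuple(flagged), threshold=min_distance
    )


@dataclass(frozen=True)
class PlateLayout:
    """Barcode/primer/reference geometry of one screening plate.

    The reference amplicon is the full PCR product between (and including)
    the target-specific primers: its prefix equals ``fwd_target_primer`` and
    its suffix equals the reverse complement of ``rev_target_primer``.
    ``cut_site`` is the 0-based offset of the expected Cas9 blunt cut within
    the reference.  ``frame_offset`` optionally gives the codon phase of the
    amplicon's coding sequence, enabling frameshift annotation.
    """

    column_barcodes: tuple[Barcode, ...]
    row_barcodes: tuple[Barcode, ...]
    fwd_target_primer: str
    rev_target_primer: str
    reference_amplicon: str
    cut_site: int
    flank: int | None = None
    frame_offset: int | None = None

    def __post_init__(self) -> None:
        cols, rows = self.column_barcodes, self.row_barcodes
        if not 1 <= len(cols) <= MAX_COLUMNS:
            raise ValueError(f"need 1..{MAX_COLUMNS} column barcodes")
        if not 1 <= len(rows) <= MAX_ROWS:
            raise ValueError(f"need 1..{MAX_ROWS} row barcodes")
        for role, group in (("column", cols), ("row", rows)):
            seqs = [b.sequence for b in group]
            if len(set(seqs)) != len(seqs):
                raise ValueError(f"duplicate {role} barcode sequence")
            for b in group:
                if b.role != role:
                    raise ValueError(f"barcode {b.id!r} has role {b.role!r}, expected {role!r}")
        ids = [b.id for b in cols + rows]
        if len(set(ids)) != len(ids):
            raise ValueError("barcode ids must be unique within a layout")
        for name, p in (("fwd", self.fwd_target_primer), ("rev", self.rev_target_primer)):
            if not is_dna(p):
                raise ValueError(f"{name} target primer must be non-empty A/C/G/T")
        ref = self.reference_amplicon
        if not is_dna(ref):
            raise ValueError("reference amplicon must be non-empty A/C/G/T")
        if len(ref) < len(self.fwd_target_primer) + len(self.rev_target_primer):
            raise ValueError("reference amplicon shorter than the two primers combined")
        if not ref.startswith(self.fwd_target_primer):
            raise ValueError("fwd_target_primer must be the reference amplicon prefix")
        if not ref.endswith(revcomp(self.rev_target_primer)):
            raise ValueError(
                "reverse complement of rev_target_primer must be the reference suffix"
            )
        if not 0 <= self.cut_site < len(ref):
            raise ValueError("cut_site outside the reference amplicon")

    @property
    def n_wells(self) -> int:
        return len(self.column_barcodes) * len(self.row_barcodes)

    @property
    def interior_start(self) -> int:
        """First reference position after the forward primer."""
        return len(self.fwd_target_primer)

    @property
    def interior_end(self) -> int:
        """Reference position where the reverse-primer region begins."""
        return len(self.reference_amplicon) - len(self.rev_target_primer)


def enumerate_wells(layout: PlateLayout) -> list[WellIdentity]:
    """All well identities in row-major order (A1, A2, ..., H12).

    Each well receives a distinct (column barcode, row barcode) pair; the
    product rule gives ``|columns| x |rows|`` wells.
    """
    wells = []
    for r, row_bc in enumerate(layout.row_barcodes):
        for c, col_bc in enumerate(layout.column_barcodes):
            wells.append(
                WellIdentity(
                    row_label=ROW_LABELS[r],
                    column_label=c + 1,
                    column_barcode_id=col_bc.id,
                    row_barcode_id=row_bc.id,
                )
            )
    return wells


def count_primers(layout: PlateLayout) -> int:
    """Number of oligos the scheme needs: one per barcode, |columns| + |rows|.

    The target-specific portion is shared, so a full 12x8 plate takes only 20
    primers for 96 uniquely barcoded amplicons.
    """
    return len(layout.column_barcodes) + len(layout.row_barcodes)


def expected_amplicon_length(layout: PlateLayout) -> int:
    """Length of the reference amplicon (2 x flank when built symmetrically)."""
    return len(layout.reference_amplicon)


def well_by_name(layout: PlateLayout) -> dict[str, WellIdentity]:
    return {w.name: w for w in enumerate_wells(layout)}
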