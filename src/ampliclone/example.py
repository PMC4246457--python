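"""Deterministic synthetic example layout.

The screen this package models used a subset of the IonXpress barcode set and
a 200 bp amplicon centred on the guide site of a real locus; neither the
barcode subset nor the amplicon sequence is published.  This module therefore
generates a *synthetic* stand-in layout: 12 column + 8 row barcodes (10 nt,
minimum pairwise edit distance 5, including against reverse complements, so
1-mismatch demultiplexing has a wide safety margin) and a random 200 bp
reference amplicon with 20 nt target primers and the cut site at its centre.

Generation is fully deterministic for a given seed, so the packaged layout is
reproducible without shipping data files.
"""

from __future__ import annotations

import numpy as np

from ._seq import revcomp
from .plate import Barcode, PlateLayout, barcode_distance

_BASES = "ACGT"

DEFAULT_SEED = 7
BARCODE_LENGTH = 10
MIN_EXAMPLE_DISTANCE = 5


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _generate_barcodes(rng: np.random.Generator, n: int) -> list[str]:
    """Rejection-sample n barcodes with pairwise edit distance >= 5.

    Distance is also enforced against every reverse complement so that a
    read entering from the opposite adaptor can never confuse the leading
    barcode matcher.
    """
    kept: list[str] = []
    pool: list[str] = []
    while len(kept) < n:
        cand = _random_seq(rng, BARCODE_LENGTH)
        if barcode_distance(cand, revcomp(cand)) < MIN_EXAMPLE_DISTANCE:
            continue
        if all(barcode_distance(cand, p) >= MIN_EXAMPLE_DISTANCE for p in pool):
            kept.append(cand)
            pool.extend((cand, revcomp(cand)))
    return kept


def example_layout(
    n_columns: int = 12,
    n_rows: int = 8,
    flank: int = 100,
    primer_length: int = 20,
    seed: int = DEFAULT_SEED,
) -> PlateLayout:
    """Build the packaged synthetic layout (defaults: full 12x8 plate, 200 bp).

    The amplicon covers ``flank`` nucleotides either side of the cut site, so
    its length is ``2 x flank`` with the cut at the midpoint.  Target primers
    are the first/last ``primer_length`` bases of the amplicon.
    """
    rng = np.random.default_rng(seed)
    seqs = _generate_barcodes(rng, n_columns + n_rows)
    columns = tuple(
        Barcode(id=f"COL{i + 1:02d}", sequence=s, role="column")
        for i, s in enumerate(seqs[:n_columns])
    )
    rows = tuple(
        Barcode(id=f"ROW{i + 1:02d}", sequence=s, role="row")
        for i, s in enumerate(seqs[n_columns:])
    )
    reference = _random_seq(rng, 2 * flank)
    return PlateLayout(
        column_barcodes=columns,
        row_barcodes=rows,
        fwd_target_primer=reference[:primer_length],
        rev_target_primer=revcomp(reference[-primer_length:]),
        reference_amplicon=reference,
        cut_site=flank,
        flank=flank,
        frame_offset=0,
    )
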