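"""File formats: layout config (YAML), FASTQ, plate maps, truth tables.

The layout config is a flat YAML document; the cut site is 1-based there
(converted to the package's internal 0-based convention on load), and the
reference amplicon may be given inline or as a FASTA path.
"""

from __future__ import annotations

import gzip
import os
from typing import Iterable, Iterator

import pandas as pd
import yaml
from Bio import SeqIO

from ._seq import revcomp
from .demux import ReadRecord
from .plate import Barcode, PlateLayout, enumerate_wells
from .simulate import TruthSet


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream a FASTQ file (plain or gzip, Sanger phred+33)."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            quals = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            yield ReadRecord(rec.id, str(rec.seq), quals)


def write_fastq(reads: Iterable[ReadRecord], path) -> int:
    """Write reads as FASTQ; returns the record count."""
    n = 0
    with _open_text(path, "wt") as out:
        for read in reads:
            quals = read.qualities or "I" * len(read.sequence)
            out.write(f"@{read.id}\n{read.sequence}\n+\n{quals}\n")
            n += 1
    return n


def load_layout(path) -> PlateLayout:
    """Load a plate layout from YAML (cut_site 1-based in the file)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    reference = doc.get("reference_amplicon")
    if reference is None:
        fasta = doc["reference_fasta"]
        if not os.path.isabs(fasta):
            fasta = os.path.join(os.path.dirname(os.path.abspath(path)), fasta)
        reference = str(next(SeqIO.parse(fasta, "fasta")).seq)
    return PlateLayout(
        column_barcodes=tuple(
            Barcode(b["id"], b["sequence"].upper(), "column")
            for b in doc["column_barcodes"]
        ),
        row_barcodes=tuple(
            Barcode(b["id"], b["sequence"].upper(), "row")
            for b in doc["row_barcodes"]
        ),
        fwd_target_primer=doc["fwd_target_primer"].upper(),
        rev_target_primer=doc["rev_target_primer"].upper(),
        reference_amplicon=reference.upper(),
        cut_site=int(doc["cut_site"]) - 1,
        flank=doc.get("flank"),
        frame_offset=doc.get("frame_offset"),
    )


def save_layout(layout: PlateLayout, path) -> None:
    doc = {
        "column_barcodes": [
            {"id": b.id, "sequence": b.sequence} for b in layout.column_barcodes
        ],
        "row_barcodes": [
            {"id": b.id, "sequence": b.sequence} for b in layout.row_barcodes
        ],
        "fwd_target_primer": layout.fwd_target_primer,
        "rev_target_primer": layout.rev_target_primer,
        "reference_amplicon": layout.reference_amplicon,
        "cut_site": layout.cut_site + 1,  # 1-based in the config file
        "flank": layout.flank,
        "frame_offset": layout.frame_offset,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_plate_map(layout: PlateLayout, path) -> pd.DataFrame:
    """TSV of well coordinates and their barcode pair."""
    rows = [
        {
            "well": w.name,
            "row": w.row_label,
            "column": w.column_label,
            "column_barcode": w.column_barcode_id,
            "row_barcode": w.row_barcode_id,
        }
        for w in enumerate_wells(layout)
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def write_truth(truth: TruthSet, path_prefix) -> None:
    """Write truth tables: <prefix>_reads.tsv and <prefix>_wells.tsv."""
    reads = pd.DataFrame(
        [
            {
                "read_id": rid,
                "well": t.well,
                "orientation": t.orientation,
                "allele_index": t.allele_index,
                "allele": t.allele_name,
            }
            for rid, t in truth.reads.items()
        ]
    )
    reads.to_csv(f"{path_prefix}_reads.tsv", sep="\t", index=False)
    wells = pd.DataFrame(
        [
            {
                "well": name,
                "true_class": truth.classes[name],
                "depth": truth.depths[name],
                "alleles": ",".join(a.name for a, _ in spec.alleles),
                "fractions": ",".join(f"{f:g}" for _, f in spec.alleles),
            }
            for name, spec in truth.wells.items()
        ]
    )
    wells.to_csv(f"{path_prefix}_wells.tsv", sep="\t", index=False)


__all__ = [
    "read_fastq",
    "write_fastq",
    "load_layout",
    "save_layout",
    "write_plate_map",
    "write_truth",
    "revcomp",
]
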