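"""The end-to-end genotyping workflow: demux -> align -> call -> summarize.

``run_pipeline`` wires the stages together over one pooled FASTQ and one
plate layout (one plate per run), optionally persisting TSV reports, SAM
per well and a run manifest recording every effective threshold.  Per-well
work is independent; with ``threads > 1`` wells are processed concurrently
(thread-based — the aligner kernel releases the GIL) with results merged in
plate order, so output is identical to serial execution.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from joblib import Parallel, delayed

from . import __version__
from .align import AlignedRead, ScoringScheme, align_read, write_reference_fasta, write_sam
from .demux import DemuxParams, DemuxResult, ReadRecord, WellAssignment, demultiplex
from .genotype import CohortSummary, GenotypeCall, make_call, summarize_cohort
from .plate import PlateLayout
from .qc import CoverageReport, coverage_qc
from .variants import (
    DEFAULT_ALPHA,
    DEFAULT_MIN_ALLELE_FRACTION,
    DEFAULT_MIN_COVERAGE,
    DEFAULT_MINOR_FLOOR,
    DEFAULT_RECURRENCE_MIN_WELLS,
    DEFAULT_SUBSTITUTION_MIN_FRACTION,
    DEFAULT_WINDOW,
    ReadSignature,
    VariantObservation,
    WellAlleleTable,
    build_allele_table,
    extract_allele,
    format_allele,
    format_variant,
    observe_variants,
    recurrence_filter,
)


@dataclass
class PipelineParams:
    """Every tunable threshold of the workflow, with screen-scale defaults."""

    demux: DemuxParams = field(default_factory=DemuxParams)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    window: int = DEFAULT_WINDOW
    min_coverage: int = DEFAULT_MIN_COVERAGE
    min_allele_fraction: float = DEFAULT_MIN_ALLELE_FRACTION
    minor_allele_floor: float = DEFAULT_MINOR_FLOOR
    strand_bias_alpha: float = DEFAULT_ALPHA
    substitution_min_fraction: float = DEFAULT_SUBSTITUTION_MIN_FRACTION
    recurrence_min_wells: int = DEFAULT_RECURRENCE_MIN_WELLS
    threads: int = 1


@dataclass
class WellResult:
    well: str
    n_reads: int  # demultiplexed to this well
    n_aligned: int
    n_unmapped: int
    table: WellAlleleTable
    call: GenotypeCall
    observations: list[VariantObservation]
    alignments: list[AlignedRead] = field(default_factory=list)


@dataclass
class PipelineResult:
    demux: DemuxResult
    wells: dict  # well name -> WellResult (only wells that received reads)
    calls: list[GenotypeCall]
    summary: CohortSummary
    qc: CoverageReport | None
    blacklist: set
    manifest: dict


def _align_well(
    name: str,
    assignments: Sequence[WellAssignment],
    layout: PlateLayout,
    params: PipelineParams,
    keep_alignments: bool,
) -> tuple[str, list[ReadSignature], list[AlignedRead], int]:
    signatures: list[ReadSignature] = []
    alignments: list[AlignedRead] = []
    unmapped = 0
    reference = layout.reference_amplicon
    for a in assignments:
        if not a.trimmed_sequence:
            unmapped += 1
            continue
        aln = align_read(
            a.trimmed_sequence,
            reference,
            params.scoring,
            read_id=a.read_id,
            orientation=a.orientation,
        )
        if aln is None:
            unmapped += 1
            continue
        signatures.append(extract_allele(aln, layout, window=params.window))
        if keep_alignments:
            alignments.append(aln)
    return name, signatures, alignments, unmapped


def run_pipeline(
    reads: Iterable[ReadRecord],
    layout: PlateLayout,
    params: PipelineParams | None = None,
    out_dir=None,
    sam_out=None,
    run_name: str = "run",
    write_bins: bool = False,
    input_paths: Sequence[str] = (),
) -> PipelineResult:
    """Run the full genotyping workflow over pooled reads.

    NO_CALL wells are results, not errors.  When fewer than two wells carry
    reads the cross-sample recurrence filter is skipped (it needs multiple
    wells by definition).
    """
    params = params or PipelineParams()
    demux_result = demultiplex(
        reads,
        layout,
        params.demux,
        out_dir=out_dir if write_bins else None,
        run_name=run_name,
    )

    occupied = [
        (name, assigned)
        for name, assigned in demux_result.assignments.items()
        if assigned
    ]
    keep_alignments = sam_out is not None
    if params.threads > 1 and len(occupied) > 1:
        aligned = Parallel(n_jobs=params.threads, backend="threading")(
            delayed(_align_well)(name, assigned, layout, params, keep_alignments)
            for name, assigned in occupied
        )
    else:
        aligned = [
            _align_well(name, assigned, layout, params, keep_alignments)
            for name, assigned in occupied
        ]

    observations_by_well = {
        name: observe_variants(signatures, alpha=params.strand_bias_alpha)
        for name, signatures, _, _ in aligned
    }
    wells_with_data = {n for n, obs in observations_by_well.items() if obs}
    if len(observations_by_well) >= 2:
        blacklist = recurrence_filter(
            observations_by_well, min_wells=params.recurrence_min_wells
        )
    else:
        blacklist = set()

    wells: dict[str, WellResult] = {}
    calls: list[GenotypeCall] = []
    for name, signatures, alignments, unmapped in aligned:
        table = build_allele_table(
            signatures,
            min_coverage=params.min_coverage,
            min_allele_fraction=params.min_allele_fraction,
            minor_floor=params.minor_allele_floor,
            alpha=params.strand_bias_alpha,
            substitution_min_fraction=params.substitution_min_fraction,
            blacklist=blacklist,
        )
        call = make_call(
            name,
            [] if table.no_call else table.alleles,
            minor_evidence=table.minor_allele_evidence,
            coding_frame_offset=layout.frame_offset,
        )
        wells[name] = WellResult(
            well=name,
            n_reads=demux_result.counts[name],
            n_aligned=len(signatures),
            n_unmapped=unmapped,
            table=table,
            call=call,
            observations=observations_by_well[name],
            alignments=alignments,
        )
        calls.append(call)

    summary = summarize_cohort(calls)
    qc_report = None
    aligned_depths = {name: w.n_aligned for name, w in wells.items()}
    if any(d > 0 for d in aligned_depths.values()):
        qc_report = coverage_qc(aligned_depths)

    manifest = _build_manifest(layout, params, input_paths, run_name)
    result = PipelineResult(
        demux=demux_result,
        wells=wells,
        calls=calls,
        summary=summary,
        qc=qc_report,
        blacklist=blacklist,
        manifest=manifest,
    )
    if out_dir is not None:
        write_reports(result, layout, out_dir, run_name=run_name)
    if sam_out is not None:
        os.makedirs(sam_out, exist_ok=True)
        write_reference_fasta(layout, os.path.join(sam_out, "amplicon.fasta"))
        for name, w in wells.items():
            if w.alignments:
                write_sam(
                    w.alignments, layout, os.path.join(sam_out, f"{run_name}_{name}.sam")
                )
    return result


def _layout_hash(layout: PlateLayout) -> str:
    blob = json.dumps(
        {
            "columns": [(b.id, b.sequence) for b in layout.column_barcodes],
            "rows": [(b.id, b.sequence) for b in layout.row_barcodes],
            "reference": layout.reference_amplicon,
            "cut_site": layout.cut_site,
        },
        sort_keys=True,
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _build_manifest(
    layout: PlateLayout,
    params: PipelineParams,
    input_paths: Sequence[str],
    run_name: str,
) -> dict:
    return {
        "tool": "ampliclone",
        "version": __version__,
        "run_name": run_name,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": list(input_paths),
        "layout_hash": _layout_hash(layout),
        "parameters": {
            "demux": asdict(params.demux),
            "scoring": asdict(params.scoring),
            "window": params.window,
            "min_coverage": params.min_coverage,
            "min_allele_fraction": params.min_allele_fraction,
            "minor_allele_floor": params.minor_allele_floor,
            "strand_bias_alpha": params.strand_bias_alpha,
            "substitution_min_fraction": params.substitution_min_fraction,
            "recurrence_min_wells": params.recurrence_min_wells,
            "frame_offset": layout.frame_offset,
            "threads": params.threads,
        },
    }


_MANIFEST_NAME = "manifest.json"


def _write_tsv(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# manifest: {_MANIFEST_NAME}\n")
        df.to_csv(fh, sep="\t", index=False)


def summary_text(summary: CohortSummary) -> str:
    c = summary.counts
    lines = [
        f"wells analysed: {summary.total}",
        f"  wildtype:               {c['WILDTYPE']}",
        f"  heterozygous:           {c['HETEROZYGOUS']}",
        f"  homozygous:             {c['HOMOZYGOUS']}",
        f"  compound heterozygous:  {c['COMPOUND_HETEROZYGOUS']}",
        f"  mixed (>2 alleles):     {c['MIXED']}",
        f"  no call:                {c['NO_CALL']}",
        f"biallelic disrupted (hom + compound het): {summary.biallelic_disrupted_count}",
        (
            f"mutated: {summary.mutated_count}/{summary.called_total} of called wells"
            f" ({100 * summary.mutation_rate:.1f}%)"
        ),
        (
            f"mutated incl. no-call: {summary.mutated_count_including_no_call}/"
            f"{summary.total} ({100 * summary.mutation_rate_including_no_call:.1f}%)"
        ),
    ]
    return "\n".join(lines)


def write_reports(
    result: PipelineResult, layout: PlateLayout, out_dir, run_name: str = "run"
) -> None:
    """Persist the TSV report suite plus the manifest that produced it.

    All positions in reports are 1-based and cut-site-relative where the
    column says so (see docs/FORMATS.md).
    """
    os.makedirs(out_dir, exist_ok=True)
    cut = layout.cut_site
    ref = layout.reference_amplicon

    with open(os.path.join(out_dir, _MANIFEST_NAME), "w") as fh:
        json.dump(
            {**result.manifest, "reports": [
                "demux_summary.tsv", "allele_table.tsv", "genotype_report.tsv",
                "cohort_summary.tsv", "qc_report.tsv", "artifacts.tsv",
            ]},
            fh,
            indent=2,
        )

    _write_tsv(
        pd.DataFrame(result.demux.summary_rows()),
        os.path.join(out_dir, "demux_summary.tsv"),
    )

    allele_rows = []
    for name in result.wells:
        w = result.wells[name]
        for rank, a in enumerate(w.table.alleles, start=1):
            allele_rows.append(
                {
                    "well": name,
                    "rank": rank,
                    "allele": format_allele(a, cut, ref),
                    "read_count": a.read_count,
                    "plus": a.plus_count,
                    "minus": a.minus_count,
                    "fraction": round(a.fraction, 4),
                    "frameshift": w.call.frameshift_status[rank - 1]
                    if rank <= len(w.call.frameshift_status)
                    else "n/a",
                }
            )
    _write_tsv(
        pd.DataFrame(
            allele_rows,
            columns=[
                "well", "rank", "allele", "read_count", "plus", "minus",
                "fraction", "frameshift",
            ],
        ),
        os.path.join(out_dir, "allele_table.tsv"),
    )

    geno_rows = [
        {
            "well": name,
            "class": w.call.genotype_class,
            "n_reads": w.n_reads,
            "n_aligned": w.n_aligned,
            "n_unmapped": w.n_unmapped,
            "alleles": " | ".join(
                format_allele(a, cut, ref) for a in w.table.alleles
            ),
            "fractions": ",".join(f"{a.fraction:.3f}" for a in w.table.alleles),
            "minor_allele_evidence": w.table.minor_allele_evidence,
        }
        for name, w in result.wells.items()
    ]
    _write_tsv(
        pd.DataFrame(
            geno_rows,
            columns=[
                "well", "class", "n_reads", "n_aligned", "n_unmapped",
                "alleles", "fractions", "minor_allele_evidence",
            ],
        ),
        os.path.join(out_dir, "genotype_report.tsv"),
    )

    s = result.summary
    _write_tsv(
        pd.DataFrame(
            [
                {"metric": "total", "value": s.total},
                *({"metric": f"class_{cls}", "value": n} for cls, n in s.counts.items()),
                {"metric": "biallelic_disrupted", "value": s.biallelic_disrupted_count},
                {"metric": "mutated", "value": s.mutated_count},
                {"metric": "mutated_including_no_call",
                 "value": s.mutated_count_including_no_call},
            ]
        ),
        os.path.join(out_dir, "cohort_summary.tsv"),
    )
    with open(os.path.join(out_dir, "cohort_summary.txt"), "w") as fh:
        fh.write(summary_text(s) + "\n")

    if result.qc is not None:
        q = result.qc
        qc_rows = [
            {
                "well": name,
                "depth": q.per_well_depth[name],
                "flagged": name in q.flagged_wells,
            }
            for name in sorted(q.per_well_depth)
        ]
        df = pd.DataFrame(qc_rows)
        df.attrs = {}
        _write_tsv(df, os.path.join(out_dir, "qc_report.tsv"))

    artifact_rows = []
    for name, w in result.wells.items():
        for flag in w.table.artifact_flags:
            artifact_rows.append(
                {
                    "well": name,
                    "variant": format_variant(flag.variant, cut, ref),
                    "reason": flag.reason,
                    "evidence": json.dumps(flag.evidence),
                }
            )
    for position, kind in sorted(result.blacklist):
        artifact_rows.append(
            {
                "well": "*",
                "variant": f"{kind}@{position - cut if position < cut else position - cut + 1:+d}",
                "reason": "recurrent_across_wells",
                "evidence": "{}",
            }
        )
    _write_tsv(
        pd.DataFrame(
            artifact_rows, columns=["well", "variant", "reason", "evidence"]
        ),
        os.path.join(out_dir, "artifacts.tsv"),
    )
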