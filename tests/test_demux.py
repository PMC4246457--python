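"""Demultiplexing: anchored barcode matching, orientation handling,
conservation, and misassignment safety."""

import itertools

import pytest

from ampliclone._seq import revcomp
from ampliclone.demux import (
    DemuxParams,
    ReadRecord,
    assign_read,
    demultiplex,
    match_barcode,
)
from ampliclone.plate import Barcode, enumerate_wells
from ampliclone.simulate import AlleleSpec, SimConfig, WellSimSpec, simulate_run


def _mutate(seq: str, pos: int, base: str) -> str:
    assert seq[pos] != base
    return seq[:pos] + base + seq[pos + 1 :]


def _build_read(layout, well, insert=None):
    """Construct an error-free plus-orientation read for a well."""
    col = {b.id: b for b in layout.column_barcodes}[well.column_barcode_id]
    row = {b.id: b for b in layout.row_barcodes}[well.row_barcode_id]
    core = insert if insert is not None else layout.reference_amplicon
    return col.sequence + core + revcomp(row.sequence)


class TestMatchBarcode:
    def test_exact_match(self, layout):
        bc = layout.column_barcodes[0]
        hit, d = match_barcode(bc.sequence + "ACGT", layout.column_barcodes, 0)
        assert hit == bc and d == 0

    def test_one_mismatch_within_tolerance(self, layout):
        bc = layout.column_barcodes[3]
        prefix = _mutate(bc.sequence, 4, "A" if bc.sequence[4] != "A" else "C")
        hit, d = match_barcode(prefix + "TTTT", layout.column_barcodes, 1)
        assert hit == bc and d == 1
        # exhaustive check: every other candidate is further away
        from ampliclone._seq import hamming
        for other in layout.column_barcodes:
            if other != bc:
                assert hamming(prefix, other.sequence) > 1

    def test_equidistant_tie_is_rejected(self):
        candidates = [
            Barcode("a", "AAAA", "column"),
            Barcode("b", "AAAT", "column"),
        ]
        # prefix AAAG: distance 1 from both
        hit, d = match_barcode("AAAGCCCC", candidates, 1)
        assert hit is None and d is None

    def test_short_prefix_skips_long_candidates(self):
        candidates = [Barcode("a", "ACGTACGTAC", "column")]
        hit, d = match_barcode("ACG", candidates, 1)
        assert hit is None


class TestAssignRead:
    def test_clean_read_plus(self, layout):
        well = enumerate_wells(layout)[5]  # A6
        read = ReadRecord("r1", _build_read(layout, well))
        a = assign_read(read, layout, DemuxParams())
        assert a.well.name == "A6"
        assert a.orientation == "plus"
        assert a.fwd_mismatches == 0 and a.rev_mismatches == 0
        # trimmed sequence is the primer-free amplicon core
        assert a.trimmed_sequence == layout.reference_amplicon[20:180]

    def test_reverse_complement_maps_to_same_well_minus(self, layout):
        well = enumerate_wells(layout)[5]
        fwd = _build_read(layout, well)
        a = assign_read(ReadRecord("r1", revcomp(fwd)), layout, DemuxParams())
        assert a.well.name == "A6"
        assert a.orientation == "minus"
        assert a.trimmed_sequence == layout.reference_amplicon[20:180]

    def test_two_barcode_errors_unassigned(self, layout):
        well = enumerate_wells(layout)[0]
        read = _build_read(layout, well)
        for pos in (1, 3):
            read = _mutate(read, pos, "A" if read[pos] != "A" else "C")
        a = assign_read(ReadRecord("r1", read), layout, DemuxParams())
        assert a.well is None
        assert a.reason == "partial"  # trailing barcode still matched

    def test_short_read_rejected(self, layout):
        a = assign_read(ReadRecord("r", "ACGT"), layout, DemuxParams())
        assert a.well is None and a.reason == "too_short"


class TestDemultiplex:
    def test_empty_input(self, layout):
        result = demultiplex([], layout)
        assert result.total_reads == 0
        assert result.assigned_reads == 0
        assert not result.unassigned

    def test_error_free_plate_fully_recovered(self, small_layout):
        wells = enumerate_wells(small_layout)
        config = SimConfig(
            layout=small_layout,
            wells={w.name: WellSimSpec(((AlleleSpec.wildtype(), 1.0),), depth=100)
                   for w in wells},
            substitution_error_rate=0.0,
            homopolymer_indel_rate=0.0,
        )
        reads, truth = simulate_run(config, seed=0)
        result = demultiplex(reads, small_layout)
        assert result.assigned_reads == len(reads)  # 100% recovery
        for name, assigned in result.assignments.items():
            for a in assigned:
                assert truth.reads[a.read_id].well == name
                assert truth.reads[a.read_id].orientation == a.orientation

    def test_conservation_under_errors(self, small_layout, rng):
        wells = enumerate_wells(small_layout)
        config = SimConfig(
            layout=small_layout,
            wells={w.name: WellSimSpec(((AlleleSpec.wildtype(), 1.0),), depth=50)
                   for w in wells},
            substitution_error_rate=0.02,
            homopolymer_indel_rate=0.01,
        )
        reads, _ = simulate_run(config, seed=3)
        result = demultiplex(reads, small_layout)
        binned = result.assigned_reads + len(result.unassigned)
        assert binned == result.total_reads == len(reads)

    def test_orientation_symmetry(self, small_layout):
        """Reverse-complementing every read swaps plus/minus labels only."""
        wells = enumerate_wells(small_layout)
        config = SimConfig(
            layout=small_layout,
            wells={w.name: WellSimSpec(((AlleleSpec.wildtype(), 1.0),), depth=30)
                   for w in wells},
            substitution_error_rate=0.01,
        )
        reads, _ = simulate_run(config, seed=4)
        flipped = [ReadRecord(r.id, revcomp(r.sequence)) for r in reads]
        fwd = demultiplex(reads, small_layout)
        rev = demultiplex(flipped, small_layout)
        flip = {"plus": "minus", "minus": "plus"}
        for name in fwd.assignments:
            a_fwd = {a.read_id: a for a in fwd.assignments[name]}
            a_rev = {a.read_id: a for a in rev.assignments[name]}
            assert set(a_fwd) == set(a_rev)  # same wells
            for rid, a in a_fwd.items():
                assert a_rev[rid].orientation == flip[a.orientation]

    def test_per_well_fastq_written(self, small_layout, tmp_path):
        wells = enumerate_wells(small_layout)
        config = SimConfig(
            layout=small_layout,
            wells={wells[0].name: WellSimSpec(((AlleleSpec.wildtype(), 1.0),), depth=5)},
            substitution_error_rate=0.0,
            homopolymer_indel_rate=0.0,
        )
        reads, _ = simulate_run(config, seed=0)
        demultiplex(reads, small_layout, out_dir=tmp_path, run_name="t")
        out = tmp_path / f"t_{wells[0].name}.fastq"
        assert out.exists()
        assert out.read_text().count("@sim:") == 5


class TestAmbiguitySafety:
    def test_error_free_misassignment_impossible_within_half_distance(self):
        """With min pairwise distance d and tolerance <= floor((d-1)/2), an
        error-free prefix can only ever match its own barcode."""
        seqs = ["AAAAAA", "AAATTT", "TTTCCC", "CCCGGG"]  # min distance 3
        candidates = [Barcode(f"b{i}", s, "column") for i, s in enumerate(seqs)]
        for true_bc in candidates:
            hit, d = match_barcode(true_bc.sequence, candidates, max_mismatch=1)
            assert hit == true_bc and d == 0
        # and for every single-error corruption, never a *wrong* barcode
        for true_bc, pos, base in itertools.product(
            candidates, range(6), "ACGT"
        ):
            if true_bc.sequence[pos] == base:
                continue
            prefix = _mutate(true_bc.sequence, pos, base)
            hit, _ = match_barcode(prefix, candidates, max_mismatch=1)
            assert hit in (true_bc, None)
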