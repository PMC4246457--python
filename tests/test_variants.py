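"""Allele extraction, strand-bias testing, recurrence filtering, collapsing."""

import pytest

from ampliclone.align import ScoringScheme, align_read
from ampliclone.variants import (
    AlleleSignature,
    ReadSignature,
    Variant,
    VariantObservation,
    build_allele_table,
    extract_allele,
    format_allele,
    format_variant,
    recurrence_filter,
    strand_bias_test,
)


def _sig(variants=(), orientation="plus", out=()):
    return ReadSignature(tuple(variants), tuple(out), orientation)


class TestExtractAllele:
    def test_perfect_read_is_wildtype(self, layout):
        ref = layout.reference_amplicon
        aln = align_read(ref[20:180], ref)
        sig = extract_allele(aln, layout)
        assert sig.is_wildtype
        assert not sig.out_of_window

    def test_one_base_deletion_at_cut_site(self, layout):
        ref = layout.reference_amplicon
        cut = layout.cut_site
        read = ref[20:cut] + ref[cut + 1 : 180]
        sig = extract_allele(align_read(read, ref), layout)
        assert len(sig.variants) == 1
        v = sig.variants[0]
        assert v.kind == "deletion" and v.length == 1
        assert abs(v.position - cut) <= 25

    def test_distal_substitution_is_candidate_artifact(self, layout):
        ref = layout.reference_amplicon
        cut = layout.cut_site
        pos = cut - 40  # outside the +/-25 window
        base = "A" if ref[pos] != "A" else "C"
        read = ref[20:pos] + base + ref[pos + 1 : 180]
        sig = extract_allele(align_read(read, ref), layout, window=25)
        assert sig.is_wildtype  # still a wildtype allele signature
        assert len(sig.out_of_window) == 1
        assert sig.out_of_window[0].kind == "substitution"
        assert sig.out_of_window[0].position == pos


class TestStrandBiasTest:
    def test_perfect_balance(self):
        p, biased = strand_bias_test(50, 50, 0.5)
        assert p == pytest.approx(1.0)
        assert not biased

    def test_forty_reads_one_strand(self):
        # closed-form two-sided tail: 2 * 0.5^40
        p, biased = strand_bias_test(40, 0, 0.5)
        assert p == pytest.approx(2 * 0.5**40, rel=1e-9)
        assert biased

    def test_extremity_guard_protects_small_counts(self):
        p, biased = strand_bias_test(3, 2, 0.5)
        assert not biased  # fraction 0.6 is not extreme, whatever p says

    def test_significant_but_not_extreme_is_not_biased(self):
        # 65/35 at n=100 rejects the null but fails the extremity guard
        p, biased = strand_bias_test(65, 35, 0.5)
        assert p < 0.01
        assert not biased

    def test_requires_support(self):
        with pytest.raises(ValueError):
            strand_bias_test(0, 0, 0.5)


def _obs(position, kind, in_window, biased, plus=20, minus=0):
    v = Variant(kind, position, 1)
    return VariantObservation(v, in_window, plus, minus, 0.001 if biased else 1.0, biased)


class TestRecurrenceFilter:
    def test_widespread_artifact_blacklisted(self):
        obs = {f"w{i}": [_obs(30, "substitution", False, True)] for i in range(10)}
        obs.update({f"x{i}": [] for i in range(10)})
        assert recurrence_filter(obs, min_wells=3) == {(30, "substitution")}

    def test_true_allele_in_two_wells_safe(self):
        obs = {
            "a": [_obs(100, "deletion", True, False, plus=30, minus=30)],
            "b": [_obs(100, "deletion", True, False, plus=30, minus=30)],
            "c": [],
        }
        assert recurrence_filter(obs, min_wells=3) == set()

    def test_no_shared_variants_empty(self):
        assert recurrence_filter({"a": [], "b": []}) == set()

    def test_in_window_balanced_never_blacklisted(self):
        # even in many wells, an in-window balanced variant stays safe
        obs = {f"w{i}": [_obs(100, "deletion", True, False, 30, 30)] for i in range(10)}
        assert recurrence_filter(obs, min_wells=3) == set()

    def test_needs_two_wells(self):
        with pytest.raises(ValueError):
            recurrence_filter({"a": []})


DEL1 = Variant("deletion", 100, 1)
DEL13 = Variant("deletion", 94, 13)


class TestBuildAlleleTable:
    def test_pure_wildtype_well(self):
        sigs = [_sig(orientation="plus" if i % 2 else "minus") for i in range(100)]
        table = build_allele_table(sigs)
        assert not table.no_call
        assert len(table.alleles) == 1
        assert table.alleles[0].is_wildtype
        assert table.alleles[0].fraction == 1.0

    def test_compound_het_balanced(self):
        sigs = []
        for v in (DEL1, DEL13):
            sigs += [_sig([v], "plus")] * 30 + [_sig([v], "minus")] * 30
        table = build_allele_table(sigs)
        assert len(table.alleles) == 2
        assert {a.fraction for a in table.alleles} == {0.5}
        assert not any(a.is_wildtype for a in table.alleles)

    def test_plus_only_substitution_flagged(self):
        sub = Variant("substitution", 101, 1, alt_base="A")
        sigs = [_sig(orientation="plus" if i % 2 else "minus") for i in range(100)]
        sigs += [_sig([sub], "plus")] * 4
        table = build_allele_table(sigs)
        assert len(table.alleles) == 1 and table.alleles[0].is_wildtype
        assert table.alleles[0].read_count == 104  # errors fold back into WT
        assert any(
            f.variant == sub and f.reason == "strand_bias"
            for f in table.artifact_flags
        )

    def test_balanced_substitution_allele_is_called(self):
        sub = Variant("substitution", 101, 1, alt_base="A")
        sigs = [_sig(orientation="plus" if i % 2 else "minus") for i in range(60)]
        sigs += [_sig([sub], "plus" if i % 2 else "minus") for i in range(60)]
        table = build_allele_table(sigs)
        assert len(table.alleles) == 2
        assert any(not a.is_wildtype for a in table.alleles)

    def test_biased_indel_removed_before_collapse(self):
        # a strand-restricted 1 nt insertion rides on half the WT reads
        ins = Variant("insertion", 103, 1, inserted_sequence="A")
        sigs = [_sig(orientation="minus")] * 100
        sigs += [_sig([ins], "plus")] * 100
        table = build_allele_table(sigs)
        assert len(table.alleles) == 1 and table.alleles[0].is_wildtype
        assert table.alleles[0].read_count == 200
        assert any(f.reason == "strand_bias" for f in table.artifact_flags)

    def test_low_coverage_no_call(self):
        table = build_allele_table([_sig()] * 50, min_coverage=100)
        assert table.no_call
        assert table.alleles == []

    def test_minor_allele_evidence(self):
        sigs = [_sig(orientation="plus" if i % 2 else "minus") for i in range(90)]
        sigs += [_sig([DEL1], "plus" if i % 2 else "minus") for i in range(10)]
        table = build_allele_table(sigs)  # del1 at 10% < 20% threshold
        assert len(table.alleles) == 1
        assert table.minor_allele_evidence
        assert table.dropped_minor_reads == 10

    def test_read_conservation(self):
        sigs = [_sig(orientation="plus" if i % 2 else "minus") for i in range(80)]
        sigs += [_sig([DEL1], "plus" if i % 2 else "minus") for i in range(12)]
        sigs += [_sig([DEL13], "plus" if i % 2 else "minus") for i in range(30)]
        table = build_allele_table(sigs)
        assert table.called_reads + table.dropped_minor_reads == len(sigs)

    def test_blacklisted_variant_removed(self):
        sigs = [_sig(orientation="plus" if i % 2 else "minus") for i in range(60)]
        sigs += [_sig([DEL1], "plus" if i % 2 else "minus") for i in range(60)]
        table = build_allele_table(sigs, blacklist={(100, "deletion")})
        assert len(table.alleles) == 1 and table.alleles[0].is_wildtype
        assert any(f.reason == "recurrent_across_wells" for f in table.artifact_flags)


class TestLeftAlignCanonicality:
    def test_homopolymer_deletions_collapse_to_one_signature(self, layout):
        """Reads deleting different bases of the same homopolymer produce
        identical signatures after left-normalized alignment."""
        ref = layout.reference_amplicon
        cut = layout.cut_site
        # build a synthetic reference with an A-run at the cut site
        run_ref = ref[: cut - 3] + "AAAAAA" + ref[cut + 3 :]
        layout2 = layout.__class__(
            column_barcodes=layout.column_barcodes,
            row_barcodes=layout.row_barcodes,
            fwd_target_primer=layout.fwd_target_primer,
            rev_target_primer=layout.rev_target_primer,
            reference_amplicon=run_ref,
            cut_site=cut,
        )
        sigs = set()
        for k in range(6):  # delete the k-th A of the run
            pos = cut - 3 + k
            read = run_ref[20:pos] + run_ref[pos + 1 : 180]
            sig = extract_allele(align_read(read, run_ref), layout2)
            sigs.add(sig.variants)
        assert len(sigs) == 1
        ((variant,),) = sigs
        assert variant.kind == "deletion" and variant.length == 1


class TestFormatting:
    def test_deletion_notation_relative_to_cut(self):
        v = Variant("deletion", 98, 13)
        assert format_variant(v, cut_site=100) == "del13@-2"

    def test_no_position_zero(self):
        assert format_variant(Variant("deletion", 100, 1), 100) == "del1@+1"
        assert format_variant(Variant("deletion", 99, 1), 100) == "del1@-1"

    def test_wildtype_allele(self):
        a = AlleleSignature((), 10, 5, 5, 1.0)
        assert format_allele(a, 100) == "WT"
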