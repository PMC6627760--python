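"""Gene-region model: coordinates, arm prediction, subregion partition."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from mirsomatic.annotation import (
    MatureArm,
    PrecursorAnnotation,
    build_gene_region,
    classify_arm_dominance,
    genomic_to_precursor,
    load_annotation,
    predict_counterpart_arm,
    region_length_accounting,
    revcomp,
)

GFF_HEADER = "##gff-version 3\n"


def _write_gff(tmp_path, lines, name="ann.gff3"):
    p = tmp_path / name
    p.write_text(GFF_HEADER + "\n".join(lines) + "\n")
    return str(p)


def _stemloop(chrom, start, end, strand, gid):
    return (f"{chrom}\tt\tmiRNA_primary_transcript\t{start}\t{end}\t.\t"
            f"{strand}\t.\tID={gid};Name={gid}")


def _mature(chrom, start, end, strand, mid, parent):
    return (f"{chrom}\tt\tmiRNA\t{start}\t{end}\t.\t{strand}\t.\t"
            f"ID={mid};Name={mid};Derives_from={parent}")


class TestLoadAnnotation:
    def test_plus_strand_mature_coordinates(self, tmp_path):
        gff = _write_gff(tmp_path, [
            _stemloop("chr1", 1001, 1080, "+", "g1"),
            _mature("chr1", 1005, 1026, "+", "g1-5p", "g1"),
            _mature("chr1", 1057, 1078, "+", "g1-3p", "g1"),
        ])
        (pre,) = load_annotation(gff, trim_to_mature=False)
        arm5 = pre.arm("5p")
        assert (arm5.start, arm5.end) == (5, 26)
        assert pre.arm("3p").is_annotated

    def test_minus_strand_equals_reverse_complemented_plus(self, tmp_path):
        # strand-flip oracle: a minus-strand mature at genomic [1055, 1076]
        # within [1001, 1080] sits at the same precursor-relative interval
        # as a plus-strand mature at the mirrored coordinates
        gff_minus = _write_gff(tmp_path, [
            _stemloop("chr1", 1001, 1080, "-", "g1"),
            _mature("chr1", 1055, 1076, "-", "g1-x", "g1"),
            _mature("chr1", 1003, 1024, "-", "g1-y", "g1"),
        ], "minus.gff3")
        # mirror: genomic pos p -> 1001 + (1080 - p)
        gff_plus = _write_gff(tmp_path, [
            _stemloop("chr1", 1001, 1080, "+", "g1"),
            _mature("chr1", 1005, 1026, "+", "g1-x", "g1"),
            _mature("chr1", 1057, 1078, "+", "g1-y", "g1"),
        ], "plus.gff3")
        (pm,) = load_annotation(gff_minus, trim_to_mature=False)
        (pp,) = load_annotation(gff_plus, trim_to_mature=False)
        rel_minus = {(a.start, a.end) for a in pm.arms}
        rel_plus = {(a.start, a.end) for a in pp.arms}
        assert rel_minus == rel_plus == {(5, 26), (57, 78)}
        assert pm.arm("5p").start == 5

    def test_trim_to_mature_bounds(self, tmp_path):
        gff = _write_gff(tmp_path, [
            _stemloop("chr1", 1001, 1080, "+", "g1"),
            _mature("chr1", 1005, 1026, "+", "g1-5p", "g1"),
            _mature("chr1", 1057, 1078, "+", "g1-3p", "g1"),
        ])
        (pre,) = load_annotation(gff)
        assert (pre.genomic_start, pre.genomic_end) == (1005, 1078)
        assert (pre.arm("5p").start, pre.arm("3p").end) == (1, pre.length)

    def test_mature_outside_stemloop_rejected(self, tmp_path):
        gff = _write_gff(tmp_path, [
            _stemloop("chr1", 1001, 1080, "+", "g1"),
            _mature("chr1", 995, 1016, "+", "g1-5p", "g1"),  # hangs over
            _stemloop("chr1", 2001, 2080, "+", "g2"),  # no matures
            _stemloop("chr1", 3001, 3080, "+", "g3"),
            _mature("chr1", 3005, 3026, "+", "g3-5p", "g3"),
        ])
        precursors = load_annotation(gff, trim_to_mature=False)
        assert [p.gene_id for p in precursors] == ["g3"]


class TestCounterpartArm:
    def test_overhang_rule_known_5p(self):
        arm = predict_counterpart_arm(80, MatureArm("5p", 5, 26))
        assert (arm.arm_label, arm.start, arm.end) == ("3p", 57, 78)
        assert not arm.is_annotated and arm.read_count == 0

    def test_rule_is_involution(self):
        arm3 = predict_counterpart_arm(80, MatureArm("5p", 5, 26))
        arm5 = predict_counterpart_arm(80, arm3)
        assert (arm5.arm_label, arm5.start, arm5.end) == ("5p", 5, 26)

    def test_duplex_has_2nt_3prime_overhangs(self):
        # independent geometric oracle on a perfect hairpin with pairing
        # i + j = L + 1: each strand's 3' end must extend exactly 2 nt past
        # the pairing partner of the other strand's 5' end
        L = 80
        pair = lambda i: L + 1 - i
        a, b = 5, 26
        arm = predict_counterpart_arm(L, MatureArm("5p", a, b))
        assert arm.end == pair(a) + 2
        assert arm.start == pair(b) + 2

    def test_clamped_to_precursor(self):
        arm = predict_counterpart_arm(60, MatureArm("5p", 1, 22))
        assert (arm.start, arm.end) == (41, 60)

    def test_degenerate_hairpin_rejected(self):
        # predicted interval [22, 30] is only 9 nt after clamping
        with pytest.raises(ValueError, match="degenerate"):
            predict_counterpart_arm(30, MatureArm("5p", 2, 11))


class TestArmDominance:
    @pytest.mark.parametrize(
        "r5,r3,expected",
        [
            (900, 100, "5p_dominant"),
            (899, 101, "balanced"),
            (0, 500, "3p_dominant"),
            (100, 900, "3p_dominant"),
            (101, 899, "balanced"),
            (500, 500, "balanced"),
        ],
    )
    def test_threshold(self, r5, r3, expected):
        assert classify_arm_dominance(r5, r3) == expected

    def test_zero_reads_balanced(self):
        assert classify_arm_dominance(0, 0) == "balanced"

    @settings(max_examples=50, deadline=None)
    @given(
        r5=st_.integers(0, 10_000),
        r3=st_.integers(0, 10_000),
        scale=st_.integers(1, 1000),
    )
    def test_scale_invariance(self, r5, r3, scale):
        assert classify_arm_dominance(r5, r3) == classify_arm_dominance(
            r5 * scale, r3 * scale
        )


def _precursor(L=80, a5=(1, 22), a3=(59, 80), r5=950, r3=50, strand="+"):
    return PrecursorAnnotation(
        gene_id="g", chromosome="chr1", strand=strand,
        genomic_start=1000, genomic_end=1000 + L - 1,
        arms=[MatureArm("5p", *a5, read_count=r5),
              MatureArm("3p", *a3, read_count=r3)],
    )


class TestGeneRegion:
    def test_partition_and_seed(self):
        region = build_gene_region(_precursor())
        L = 80
        covered = sorted(
            p
            for label in ("guide", "passenger", "loop")
            for s, e in region.subregions[label]
            for p in range(s, e + 1)
        )
        assert covered == list(range(1, L + 1))
        assert region.subregions["flank5"] == [(-24, 0)]
        assert region.subregions["flank3"] == [(81, 105)]
        assert region.subregions["seed"] == [(2, 8)]
        assert region.arm_class == "5p_dominant"

    def test_balanced_both_arms_guide(self):
        region = build_gene_region(_precursor(r5=500, r3=500))
        assert region.subregions["passenger"] == []
        assert len(region.subregions["guide"]) == 2
        assert region.subregions["seed"] == [(2, 8), (60, 66)]

    def test_3p_dominant_seed_in_3p_arm(self):
        region = build_gene_region(_precursor(r5=50, r3=950))
        assert region.subregions["guide"] == [(59, 80)]
        assert region.subregions["seed"] == [(60, 66)]

    def test_basal_residue_absorbed_into_arm_regions(self):
        # arms not touching the precursor ends: partition must still hold
        region = build_gene_region(_precursor(a5=(5, 26), a3=(57, 78)))
        assert region.subregions["guide"] == [(1, 26)]
        assert region.subregions["passenger"] == [(57, 80)]
        assert region.subregions["loop"] == [(27, 56)]
        assert region.subregions["seed"] == [(6, 12)]

    def test_seed_is_7nt_and_inside_guide(self, clean_cohort):
        for region in clean_cohort.regions:
            for s, e in region.subregions["seed"]:
                assert e - s + 1 == 7
                assert any(gs <= s and e <= ge
                           for gs, ge in region.subregions["guide"])

    def test_overlapping_arms_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            build_gene_region(_precursor(a5=(1, 45), a3=(40, 80)))

    def test_cleavage_windows(self):
        region = build_gene_region(_precursor())
        windows = dict(region.cleavage_windows)
        assert windows["drosha5"] == (-1, 3)
        assert windows["drosha3"] == (78, 82)
        assert windows["dicer5"] == (20, 24)
        assert windows["dicer3"] == (57, 61)


class TestLengthAccounting:
    def test_flank_totals_scale_with_cohort(self, clean_cohort):
        regions = clean_cohort.regions
        lengths = region_length_accounting(regions, 569)
        assert lengths["flank5"] == 25 * len(regions) * 569
        assert lengths["flank3"] == lengths["flank5"]

    def test_disjoint_labels_sum_to_total(self, clean_cohort):
        lengths = region_length_accounting(clean_cohort.regions, 3)
        expected_total = sum(
            (r.length + 2 * r.flank_len) * 3 for r in clean_cohort.regions
        )
        assert lengths["total"] == expected_total

    def test_single_gene_single_sample(self):
        lengths = region_length_accounting([build_gene_region(_precursor())], 1)
        assert lengths["flank5"] == 25
        assert lengths["total"] == 80 + 50


def test_genomic_to_precursor_strands():
    plus = _precursor()
    minus = _precursor(strand="-")
    assert genomic_to_precursor(1000, plus) == 1
    assert genomic_to_precursor(1079, minus) == 1
    assert genomic_to_precursor(1000, minus) == 80


def test_revcomp():
    assert revcomp("ACGT") == "ACGT"
    assert revcomp("AAGC") == "GCTT"
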