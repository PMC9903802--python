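"""Breakend annotation: arms, foldbacks, LOH runs, LINE evidence, phasing."""

import pytest

from svweave.annotate import (
    AnnotationSet,
    annotate_arms_and_geometry,
    annotate_fragile_sites_and_line_sources,
    annotate_loh_and_allele_cn,
    annotate_phasing,
    annotate_sample,
    detect_foldbacks,
    has_polya_signal,
)
from svweave.config import Config
from svweave.genome_model import (
    CopyNumberProfile,
    CopyNumberSegment,
    KnowledgeBase,
)


class TestPolyA:
    @pytest.mark.parametrize("seq,expect", [
        ("A" * 11, True),
        ("T" * 11, True),
        ("AAAAAGAAAAA", True),           # 10/11 A
        ("AAAAAGGAAAA", False),          # 9/11 A
        ("ACGT" * 10, False),
        ("A" * 10, False),               # below minimum length
        ("GC" * 5 + "A" * 15 + "GC", True),
    ])
    def test_signal(self, seq, expect):
        assert has_polya_signal(seq) is expect


class TestArmsAndFoldbacks:
    def test_arm_and_unknown_chromosome(self, karyotype, junction_factory):
        j = junction_factory("j1", "chr1", 1_000_000, 1, "chr1", 30_000_000, -1)
        ann = annotate_arms_and_geometry([j], karyotype)
        assert ann.of(j.start).arm == "P"
        assert ann.of(j.end).arm == "Q"
        bad = junction_factory("j2", "chrZ", 100, 1)
        with pytest.raises(KeyError, match="chrZ"):
            annotate_arms_and_geometry([bad], karyotype)

    def test_simple_foldback_within_distance(self, karyotype, junction_factory):
        j = junction_factory("f", "chr3", 1_000_000, 1, "chr3", 1_000_800, 1)
        ann = annotate_arms_and_geometry([j], karyotype)
        detect_foldbacks([j], ann, max_distance=5000)
        assert ann.of(j.start).is_foldback and ann.of(j.end).is_foldback

    def test_distant_inversion_not_foldback(self, karyotype, junction_factory):
        j = junction_factory("f", "chr3", 1_000_000, 1, "chr3", 1_040_000, 1)
        ann = annotate_arms_and_geometry([j], karyotype)
        detect_foldbacks([j], ann, max_distance=5000)
        assert not ann.of(j.start).is_foldback

    def test_chained_foldback_via_assembly(self, karyotype, junction_factory):
        """Two same-orientation translocation breakends sharing an assembly
        phase group within range form a chained foldback."""
        a = junction_factory("t1", "chr3", 500, 1, "chr2", 9_000_000, -1, asm1=["asm1"])
        b = junction_factory("t2", "chr3", 900, 1, "chr4", 7_000_000, -1, asm1=["asm1"])
        ann = annotate_arms_and_geometry([a, b], karyotype)
        detect_foldbacks([a, b], ann, max_distance=5000)
        assert ann.of(a.start).is_foldback
        assert ann.of(a.start).foldback_partner == b.start.id

    def test_foldback_marking_symmetric(self, karyotype, junction_factory):
        js = [junction_factory("f", "chr3", 1_000_000, 1, "chr3", 1_000_800, 1),
              junction_factory("g", "chr3", 2_000_000, -1, "chr3", 2_001_000, -1)]
        ann = annotate_arms_and_geometry(js, karyotype)
        detect_foldbacks(js, ann)
        for j in js:
            for b in j.breakends:
                partner = ann.of(b).foldback_partner
                assert ann.breakends[partner].foldback_partner == b.id


class TestLohRuns:
    def _profile(self, segs):
        return CopyNumberProfile(segs)

    def test_homdel_bounding_pair_is_own_junction(self, karyotype, junction_factory):
        segs = [CopyNumberSegment("chr1", 1, 1001, 2, 1),
                CopyNumberSegment("chr1", 1001, 5001, 0, 0),
                CopyNumberSegment("chr1", 5001, 50_000_001, 2, 1)]
        j = junction_factory("d", "chr1", 1000, 1, "chr1", 5001, -1)
        ann = annotate_arms_and_geometry([j], karyotype)
        runs = annotate_loh_and_allele_cn([j], self._profile(segs), ann)
        homdel = [r for r in runs if r.kind == "homdel"]
        assert len(homdel) == 1
        assert {homdel[0].left_breakend, homdel[0].right_breakend} == {"d_a", "d_b"}

    def test_loh_run_bounded_by_two_junctions(self, karyotype, junction_factory):
        """Brute-force check: every segment inside the reported run has minor
        CN below the LOH threshold."""
        segs = [CopyNumberSegment("chr1", 1, 10_000, 2, 1),
                CopyNumberSegment("chr1", 10_000, 200_000, 2, 0.0),
                CopyNumberSegment("chr1", 200_000, 50_000_001, 2, 1)]
        trl = junction_factory("t", "chr1", 9_999, 1, "chr2", 5_000_000, -1)
        inv = junction_factory("i", "chr1", 200_000, -1, "chr1", 400_000, -1)
        profile = self._profile(segs)
        ann = annotate_arms_and_geometry([trl, inv], karyotype)
        runs = annotate_loh_and_allele_cn([trl, inv], profile, ann)
        loh = [r for r in runs if r.kind == "loh"]
        assert len(loh) == 1
        assert loh[0].left_breakend == "t_a" and loh[0].right_breakend == "i_a"
        for s in profile.segments("chr1"):
            if s.start >= loh[0].start and s.end <= loh[0].end:
                assert s.cn_minor < 0.5

    def test_telomeric_run_single_sided(self, karyotype, junction_factory):
        segs = [CopyNumberSegment("chr1", 1, 1_000_000, 1, 0),
                CopyNumberSegment("chr1", 1_000_000, 50_000_001, 2, 1)]
        j = junction_factory("t", "chr1", 1_000_000, -1, "chr2", 5_000_000, 1)
        ann = annotate_arms_and_geometry([j], karyotype)
        runs = annotate_loh_and_allele_cn([j], self._profile(segs), ann)
        loh = [r for r in runs if r.kind == "loh"]
        assert loh[0].left_breakend is None
        assert loh[0].right_breakend == "t_a"

    def test_high_major_run_detected(self, karyotype, junction_factory):
        segs = [CopyNumberSegment("chr1", 1, 10_000, 2, 1),
                CopyNumberSegment("chr1", 10_000, 20_000, 7, 1),
                CopyNumberSegment("chr1", 20_000, 50_000_001, 2, 1)]
        a = junction_factory("a", "chr1", 10_000, -1, "chr2", 1_000_000, 1, jcn=5)
        b = junction_factory("b", "chr1", 19_999, 1, "chr2", 2_000_000, 1, jcn=5)
        ann = annotate_arms_and_geometry([a, b], karyotype)
        runs = annotate_loh_and_allele_cn([a, b], self._profile(segs), ann)
        high = [r for r in runs if r.kind == "high_major"]
        assert len(high) == 1 and high[0].left_breakend == "a_a" \
            and high[0].right_breakend == "b_a"


class TestLineSources:
    def test_known_source_and_fragile_site(self, karyotype, junction_factory):
        kb = KnowledgeBase(fragile_sites=[("chr1", 1000, 2000)],
                           line_sources=[("chr2", 5000, 11_000)])
        j = junction_factory("j", "chr1", 1500, 1, "chr2", 6000, -1)
        ann = annotate_arms_and_geometry([j], karyotype)
        annotate_fragile_sites_and_line_sources([j], kb, ann)
        assert ann.of(j.start).in_fragile_site
        assert ann.of(j.end).line_source == "known"

    def test_suspected_source_needs_two_polya_junctions(self, karyotype, junction_factory):
        def polya_trl(jid, pos):
            j = junction_factory(jid, "chr3", pos, 1, "chr1", 1_000_000 + hash(jid) % 1000, -1)
            j.end.insert_sequence = "A" * 15
            return j
        js = [polya_trl("a", 100_000), polya_trl("b", 103_000), polya_trl("c", 104_000)]
        ann = annotate_arms_and_geometry(js, karyotype)
        annotate_fragile_sites_and_line_sources(js, KnowledgeBase(), ann)
        assert ann.of(js[0].start).line_source == "suspected"

        lone = polya_trl("x", 40_000_000)
        ann2 = annotate_arms_and_geometry([lone], karyotype)
        annotate_fragile_sites_and_line_sources([lone], KnowledgeBase(), ann2)
        assert ann2.of(lone.start).line_source == "none"


class TestPhasing:
    def test_cis_facing_distance(self, karyotype, junction_factory):
        a = junction_factory("a", "chr1", 1000, 1, "chr2", 5_000_000, -1, asm1=["p1"])
        b = junction_factory("b", "chr1", 1201, -1, "chr2", 6_000_000, 1, asm1=["p1"])
        ann = annotate_arms_and_geometry([a, b], karyotype)
        pairs = annotate_phasing([a, b], ann, max_separation=1000)
        pair = next(p for p in pairs if {p.breakend_a, p.breakend_b} == {"a_a", "b_a"})
        assert pair.label == "cis" and pair.distance == 200

    def test_overlapping_breakends_negative_distance(self, karyotype, junction_factory):
        """Insertion-site breakends overlapping by 16 bases (target-site
        duplication) report distance -16."""
        a = junction_factory("a", "chr1", 1016, 1)     # +1 at the higher position
        b = junction_factory("b", "chr1", 1001, -1)
        ann = annotate_arms_and_geometry([a, b], karyotype)
        pairs = annotate_phasing([a, b], ann)
        assert pairs[0].distance == -16

    def test_no_assembly_means_unknown_and_no_contradiction(self, karyotype, junction_factory):
        a = junction_factory("a", "chr1", 1000, 1)
        b = junction_factory("b", "chr1", 1300, -1)
        ann = annotate_arms_and_geometry([a, b], karyotype)
        pairs = annotate_phasing([a, b], ann)
        assert pairs[0].label == "unknown"
        labels = [p.label for p in pairs if {p.breakend_a, p.breakend_b} == {"a_a", "b_a"}]
        assert len(set(labels)) == 1     # a pair cannot be both cis and trans

    def test_disjoint_assemblies_trans(self, karyotype, junction_factory):
        a = junction_factory("a", "chr1", 1000, 1, asm1=["p1"])
        b = junction_factory("b", "chr1", 1300, -1, asm1=["p2"])
        ann = annotate_arms_and_geometry([a, b], karyotype)
        pairs = annotate_phasing([a, b], ann)
        assert pairs[0].label == "trans"
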