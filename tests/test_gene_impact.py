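"""Transcript context, fusions, disruptions, IG events, drivers, enrichment."""

import math

import pytest

from svweave.config import Config
from svweave.gene_impact import (
    annotate_breakend_genes,
    call_disruptions_and_homozygous,
    call_fusions,
    call_ig_rearrangements,
    match_drivers,
    poisson_upper_tail,
)
from svweave.gene_impact import test_homdisruption_enrichment as enrichment_test
from svweave.genome_model import IgRegion, KnowledgeBase
from svweave.pipeline import run_sample
from svweave.simulate import simulate_enrichment_cohort

# FUS5 (chr1 @8M, +): 10 exons of 200, introns 5000, coding 8000030..
# intron k spans (8000000 + (k-1)*5200 + 199, 8000000 + k*5200)
FUS5_INTRON1 = 8_002_000
# FUS3 (chr2 @8M, +): intron 10 between exon 10 end and exon 11 start
FUS3_INTRON10 = 8_048_000
FUS3_INTRON2 = 8_007_000
# TSG1 (chr3 @30M, +, 8 exons of 300, introns 4000): intron 5
TSG1_INTRON5 = 30_018_000


class TestBreakendContext:
    def test_intronic_context_and_phase(self, gene_model, junction_factory, config):
        j = junction_factory("j", "chr1", FUS5_INTRON1, 1, "chr2", 30_000_000, -1)
        anns = annotate_breakend_genes([j], gene_model, config)["j_a"]
        a = next(x for x in anns if x.gene == "FUS5")
        assert a.context == "intronic" and a.index == 1
        assert a.phase == a.phase % 3   # defined phase in coding region
        assert a.disruptive

    def test_same_intron_deletion_non_disruptive(self, gene_model, junction_factory,
                                                 config):
        j = junction_factory("d", "chr1", 8_001_000, 1, "chr1", 8_002_000, -1)
        anns = annotate_breakend_genes([j], gene_model, config)
        assert all(not a.disruptive for a in anns["d_a"] if a.gene == "FUS5")
        assert all(not a.disruptive for a in anns["d_b"] if a.gene == "FUS5")

    def test_upstream_window(self, gene_model, junction_factory, config):
        j = junction_factory("u", "chr1", 7_990_000, 1, "chr2", 30_000_000, -1)
        anns = annotate_breakend_genes([j], gene_model, config)["u_a"]
        assert any(a.context == "upstream" and a.gene == "FUS5" for a in anns)


class TestFusions:
    kb = KnowledgeBase(known_fusion_pairs=[("FUS5", "FUS3")])

    def _run(self, junctions, uniform_profile, karyotype, gene_model,
             kb=None):
        return run_sample(junctions, uniform_profile(), karyotype, gene_model,
                          kb or self.kb)

    def test_direct_in_frame_fusion(self, uniform_profile, karyotype, gene_model,
                                    junction_factory):
        j = junction_factory("f", "chr1", FUS5_INTRON1, 1, "chr2", FUS3_INTRON10, -1)
        res = self._run([j], uniform_profile, karyotype, gene_model)
        f = next(x for x in res.fusions if x.gene_5p == "FUS5" and x.gene_3p == "FUS3")
        assert f.in_frame and f.links == 1 and f.reportable
        assert f.match == "known_pair"

    def test_phase_mismatch_not_in_frame(self, uniform_profile, karyotype,
                                         gene_model, junction_factory):
        j = junction_factory("f", "chr1", FUS5_INTRON1, 1, "chr2", FUS3_INTRON2, -1)
        res = self._run([j], uniform_profile, karyotype, gene_model)
        f = next(x for x in res.fusions if x.gene_3p == "FUS3")
        assert not f.in_frame

    def test_chained_fusion_through_shard_counts_two_links(self, uniform_profile,
                                                           karyotype, gene_model,
                                                           junction_factory):
        a = junction_factory("h1", "chr1", FUS5_INTRON1, 1, "chr3", 1_000_000, -1)
        b = junction_factory("h2", "chr3", 1_000_500, 1, "chr2", FUS3_INTRON10, -1)
        res = self._run([a, b], uniform_profile, karyotype, gene_model)
        f = next(x for x in res.fusions if x.gene_5p == "FUS5" and x.gene_3p == "FUS3")
        assert f.links == 2 and f.in_frame

    def test_wrong_orientation_no_fusion(self, uniform_profile, karyotype,
                                         gene_model, junction_factory):
        j = junction_factory("f", "chr1", FUS5_INTRON1, -1, "chr2", FUS3_INTRON10, -1)
        res = self._run([j], uniform_profile, karyotype, gene_model)
        assert not [x for x in res.fusions
                    if x.gene_5p == "FUS5" and x.gene_3p == "FUS3"]

    def test_self_fusion_same_intron_in_frame(self, uniform_profile, karyotype,
                                              gene_model, junction_factory):
        """Identity property: joining a transcript's intron back to itself
        preserves frame."""
        j = junction_factory("s", "chr1", FUS5_INTRON1, 1, "chr1", FUS5_INTRON1 + 100,
                             -1)
        res = run_sample([j], uniform_profile(), karyotype, gene_model,
                         KnowledgeBase(promiscuous_5p=["FUS5"]))
        same = [x for x in res.fusions
                if x.gene_5p == "FUS5" and x.gene_3p == "FUS5"]
        assert same and all(x.in_frame for x in same)

    def test_readthrough_like_promiscuous_not_reported(self, uniform_profile,
                                                       karyotype, junction_factory):
        """Two same-chromosome genes under 1 Mb apart: a promiscuous match is
        flagged read-through-like and withheld from reporting."""
        from svweave.genome_model import GeneModelCollection
        from svweave.simulate import _make_gene
        gm = GeneModelCollection([
            _make_gene("NBR1", "chr1", "+", 8_000_000, 6, 200, 4_000),
            _make_gene("NBR2", "chr1", "+", 8_500_000, 6, 200, 4_000),
        ])
        kb = KnowledgeBase(promiscuous_5p=["NBR1"])
        j = junction_factory("r", "chr1", 8_006_000, 1, "chr1", 8_506_000, -1)
        res = run_sample([j], uniform_profile(), karyotype, gm, kb)
        cand = [x for x in res.fusions if x.gene_5p == "NBR1" and x.gene_3p == "NBR2"]
        assert cand and cand[0].readthrough_like and not cand[0].reportable


class TestDisruptions:
    panel = ["TSG1"]

    def test_reciprocal_translocation_homozygous(self, uniform_profile, karyotype,
                                                 gene_model, junction_factory,
                                                 config):
        """Reciprocal break through intron 5 at CN 2: both derivatives
        truncate the gene, no undisrupted copy remains, yet exonic CN
        stays 2."""
        a = junction_factory("r1", "chr3", TSG1_INTRON5, 1, "chr4", 10_000_000, -1)
        b = junction_factory("r2", "chr3", TSG1_INTRON5 + 1, -1, "chr4", 10_000_001, 1)
        anns = annotate_breakend_genes([a, b], gene_model, config)
        (call,) = call_disruptions_and_homozygous([a, b], uniform_profile(), anns,
                                                  gene_model, self.panel, config)
        assert call.min_exonic_cn == pytest.approx(2.0)
        assert call.undisrupted_copies == pytest.approx(0.0)
        assert call.homozygous

    def test_single_translocation_leaves_one_copy(self, uniform_profile, karyotype,
                                                  gene_model, junction_factory,
                                                  config):
        a = junction_factory("r1", "chr3", TSG1_INTRON5, 1, "chr4", 10_000_000, -1)
        anns = annotate_breakend_genes([a], gene_model, config)
        (call,) = call_disruptions_and_homozygous([a], uniform_profile(), anns,
                                                  gene_model, self.panel, config)
        assert call.undisrupted_copies == pytest.approx(1.0)
        assert not call.homozygous

    @pytest.mark.parametrize("cn,expect", [(2.0, False), (1.0, True)])
    def test_exonic_duplication_depends_on_copy_number(self, uniform_profile,
                                                       karyotype, gene_model,
                                                       junction_factory, config,
                                                       cn, expect):
        """A tandem duplication spanning exon 2 with both breakends inside
        the transcript disrupts one copy: homozygous only when a single copy
        existed."""
        dup = junction_factory("u", "chr3", 30_003_000, -1, "chr3", 30_007_000, 1)
        anns = annotate_breakend_genes([dup], gene_model, config)
        minor = 1.0 if cn >= 2 else 0.0
        (call,) = call_disruptions_and_homozygous([dup], uniform_profile(cn, minor),
                                                  anns, gene_model, self.panel,
                                                  config)
        assert call.homozygous is expect


class TestIgAndDrivers:
    def kb(self):
        return KnowledgeBase(
            ig_regions=[IgRegion("IGH", "chr2", 40_000_000, 41_000_000, 1)],
            driver_panel=["ONC1"])

    def test_ig_event_called_with_required_orientation(self, gene_model,
                                                       junction_factory, config):
        # ONC1 on chr3 + strand at 5,000,000; partner 50 kb upstream toward it
        j = junction_factory("ig", "chr2", 40_500_000, 1, "chr3", 4_950_000, -1)
        events = call_ig_rearrangements([j], self.kb(), gene_model, config)
        assert [e.oncogene for e in events] == ["ONC1"]

    def test_wrong_orientation_or_no_partner_rejected(self, gene_model,
                                                      junction_factory, config):
        wrong = junction_factory("w", "chr2", 40_500_000, -1, "chr3", 4_950_000, -1)
        assert not call_ig_rearrangements([wrong], self.kb(), gene_model, config)
        both_ig = junction_factory("b", "chr2", 40_500_000, 1, "chr2", 40_600_000, 1)
        assert not call_ig_rearrangements([both_ig], self.kb(), gene_model, config)

    def test_amp_driver_links_to_amplifying_cluster(self, config):
        """A gene inside simulated ecDNA loop segments is an AMP driver
        linked to the loop's cluster."""
        from svweave.simulate import EventSpec, simulate_sample
        sample = simulate_sample([EventSpec("ecdna", {"chromosome": "chr3"})], seed=17)
        kb = KnowledgeBase(driver_panel=["AMPG"])
        from svweave.genome_model import GeneModelCollection
        from svweave.simulate import _make_gene
        seg = next(s for ev in sample.truth for s in ev.footprints)
        gm = GeneModelCollection([
            _make_gene("AMPG", seg[0], "+", seg[1] + 1_000, 3, 200, 2_000)])
        res = run_sample(sample.junctions, sample.profile, sample.karyotype, gm, kb)
        amp = [m for m in res.drivers if m.driver_type == "AMP"]
        assert amp and amp[0].gene == "AMPG" and amp[0].cluster_ids


class TestEnrichment:
    def brute_force_tail(self, k, lam, terms=400):
        """Independent series summation of the upper Poisson tail."""
        if k <= 0:
            return 1.0
        log_term = -lam + k * math.log(lam) - math.lgamma(k + 1)
        total = 0.0
        term = math.exp(log_term)
        for i in range(k, k + terms):
            total += term
            term *= lam / (i + 1)
        return total

    @pytest.mark.parametrize("k,lam", [(5, 1 / 30), (1, 0.5), (12, 2.0), (40, 8.0)])
    def test_upper_tail_matches_series_oracle(self, k, lam):
        assert poisson_upper_tail(k, lam) == pytest.approx(
            self.brute_force_tail(k, lam), abs=1e-12)

    def test_zero_observed_gives_p_one(self):
        assert poisson_upper_tail(0, 3.0) == 1.0
        res = enrichment_test({"g": 0}, {"g": 1e6})
        assert res[0].p == 1.0

    def test_bh_q_monotone_and_above_p(self):
        counts, lengths = simulate_enrichment_cohort(seed=3)
        res = enrichment_test(counts, lengths)
        by_p = sorted(res, key=lambda r: r.p)
        assert all(r.q >= r.p - 1e-12 for r in res)
        qs = [r.q for r in by_p]
        assert qs == sorted(qs)

    def test_tenfold_enriched_gene_recovered(self):
        hits = 0
        for seed in range(10):
            counts, lengths = simulate_enrichment_cohort(seed=seed)
            res = enrichment_test(counts, lengths)
            hits += any(r.gene == "G000" and r.significant for r in res)
        assert hits >= 9


class TestExonRearrangements:
    def test_pathogenic_exon_deletion_matched(self, gene_model, junction_factory):
        """A deletion spanning exons 2-3 of TSG1 matches a knowledgebase
        entry for that exon range."""
        from svweave.gene_impact import call_exon_rearrangements
        # TSG1 exons k: [30M+(k-1)*4300, +299]; delete exons 2..3 fully
        j = junction_factory("d", "chr3", 30_004_000, 1, "chr3", 30_009_000, -1)
        kb = KnowledgeBase(pathogenic_exon_rearrangements=[("TSG1", 2, 3, "DEL")])
        (call,) = call_exon_rearrangements([j], gene_model, kb)
        assert (call.first_exon, call.last_exon) == (2, 3)
        assert call.known_pathogenic

    def test_wrong_type_or_range_not_pathogenic(self, gene_model, junction_factory):
        from svweave.gene_impact import call_exon_rearrangements
        dup = junction_factory("u", "chr3", 30_004_000, -1, "chr3", 30_009_000, 1)
        kb = KnowledgeBase(pathogenic_exon_rearrangements=[("TSG1", 2, 3, "DEL")])
        calls = call_exon_rearrangements([dup], gene_model, kb)
        assert calls and not calls[0].known_pathogenic
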