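"""Event classification: dispatch totality, two-break resolution, shards,
LINE/pseudogene, ecDNA/BFB."""

import pytest

from svweave.annotate import annotate_sample
from svweave.chain import enumerate_facing_pairs, allocate_links, build_chains
from svweave.classify import (
    annotate_amplification_mechanism,
    detect_ecdna,
    detect_pseudogene,
    detect_shards,
    resolve_cluster,
    resolve_two_break,
)
from svweave.cluster import Cluster, cluster_all
from svweave.config import Config
from svweave.genome_model import KnowledgeBase
from svweave.pipeline import run_sample
from svweave.simulate import (
    ALL_EVENT_KINDS,
    EventSpec,
    simulate_sample,
    toy_gene_model,
)


def resolve_simulated(kind, seed=1, params=None):
    sample = simulate_sample([EventSpec(kind, params or {})], seed=seed)
    result = run_sample(sample.junctions, sample.profile, sample.karyotype,
                        sample.gene_model, sample.knowledgebase)
    return sample, result


class TestDispatch:
    def test_lone_del_and_dup(self, uniform_profile, karyotype, junction_factory,
                              config):
        for jid, svt, o1, o2 in [("d", "DEL", 1, -1), ("u", "DUP", -1, 1)]:
            j = junction_factory(jid, "chr1", 1_000_000, o1, "chr1", 1_050_000, o2)
            res = run_sample([j], uniform_profile(), karyotype)
            assert res.resolutions[0].label == svt

    def test_lone_single_breakend(self, uniform_profile, karyotype,
                                  junction_factory):
        j = junction_factory("s", "chr1", 1_000_000, 1)
        res = run_sample([j], uniform_profile(), karyotype)
        assert res.resolutions[0].label == "SINGLE"

    def test_three_junctions_default_complex(self, uniform_profile, karyotype,
                                             junction_factory):
        js = [junction_factory(f"j{i}", "chr1", 1_000_000 + i * 1000, 1,
                               "chr2", 30_000_000 + i * 1000, -1)
              for i in range(3)]
        res = run_sample(js, uniform_profile(), karyotype)
        assert res.resolutions[0].label == "COMPLEX"

    def test_inconsistent_two_break_incomplete(self, uniform_profile, karyotype,
                                               junction_factory):
        """Two same-pattern inversions cannot chain into consistent
        derivatives."""
        a = junction_factory("a", "chr1", 1_000_000, 1, "chr1", 1_001_000, 1)
        b = junction_factory("b", "chr1", 1_000_200, 1, "chr1", 1_000_900, 1)
        res = run_sample([a, b], uniform_profile(), karyotype)
        assert res.resolutions[0].label == "INCOMPLETE"

    @pytest.mark.parametrize("kind", ALL_EVENT_KINDS)
    def test_every_simulated_cluster_gets_exactly_one_label(self, kind):
        sample, result = resolve_simulated(kind, seed=21)
        for cl in result.clusters:
            assert result.resolutions[cl.id].label in {
                "DEL", "DUP", "SYNTH_DEL", "SYNTH_DUP", "SYNTH_TRL", "RECIP_INV",
                "RECIP_TRL", "RECIP_DUP", "INS", "LINE", "PSEUDOGENE", "COMPLEX",
                "DOUBLE_MINUTE", "SGL_PAIR", "INCOMPLETE", "SINGLE"}


class TestTwoBreak:
    def test_canonical_reciprocal_translocation(self, junction_factory, config):
        a = junction_factory("a", "chr1", 100, 1, "chr2", 200, -1)
        b = junction_factory("b", "chr1", 101, -1, "chr2", 199, 1)
        out = resolve_two_break([a, b], [], config)
        assert out.label == "RECIP_TRL"

    def test_reciprocal_duplication_facing_overlap(self, junction_factory, config):
        """Facing breakends with megabase overlap at both loci."""
        a = junction_factory("a", "chr1", 3_000_000, 1, "chr2", 5_000_000, -1)
        b = junction_factory("b", "chr1", 1_000_000, -1, "chr2", 6_000_000, 1)
        out = resolve_two_break([a, b], [], config)
        assert out.label == "RECIP_DUP"

    def test_reciprocal_inversion(self, junction_factory, config):
        a = junction_factory("a", "chr1", 999_999, 1, "chr1", 2_000_000, 1)
        b = junction_factory("b", "chr1", 1_000_000, -1, "chr1", 2_000_001, -1)
        out = resolve_two_break([a, b], [], config)
        assert out.label == "RECIP_INV"

    def test_synthetic_del_with_shard(self, config):
        """Two translocations chaining through a sub-kilobase templated
        insertion reduce to a deletion."""
        sample, result = resolve_simulated("shard_del", seed=6,
                                           params={"shard_length": 500})
        (res,) = [r for r in result.resolutions.values() if r.label != "SINGLE"]
        assert res.label == "SYNTH_DEL"
        assert len(res.shards) == 1 and res.shards[0].length <= 501


class TestShards:
    def test_short_traversal_is_shard_long_is_not(self, config, junction_factory,
                                                  uniform_profile, karyotype):
        for length, expect in [(500, 1), (50_000, 0)]:
            a = junction_factory("a", "chr1", 1_000_000, 1, "chr3", 2_000_000, -1)
            b = junction_factory("b", "chr3", 2_000_000 + length, 1,
                                 "chr1", 1_100_000, -1)
            ann = annotate_sample([a, b], karyotype, uniform_profile(),
                                  KnowledgeBase(), config)
            cands = enumerate_facing_pairs([a, b], uniform_profile(), ann, config)
            chains = allocate_links([a, b], cands, uniform_profile(), karyotype,
                                    config)
            shards = [s for ch in chains for s in detect_shards(ch, [a, b], config)]
            assert len(shards) == expect

    def test_two_consecutive_shards_both_reported(self, config, junction_factory,
                                                  uniform_profile, karyotype):
        """A chain hopping through ~200-base pieces of two different
        chromosomes reports both shards."""
        a = junction_factory("a", "chr1", 1_000_000, 1, "chr3", 2_000_000, -1)
        b = junction_factory("b", "chr3", 2_000_200, 1, "chr4", 5_000_000, -1)
        c = junction_factory("c", "chr4", 5_000_200, 1, "chr1", 1_100_000, -1)
        js = [a, b, c]
        ann = annotate_sample(js, karyotype, uniform_profile(), KnowledgeBase(),
                              config)
        cands = enumerate_facing_pairs(js, uniform_profile(), ann, config)
        chains = allocate_links(js, cands, uniform_profile(), karyotype, config)
        shards = [s for ch in chains for s in detect_shards(ch, js, config)]
        assert sorted(s.chromosome for s in shards) == ["chr3", "chr4"]
        assert all(s.length == 201 for s in shards)


class TestLine:
    def test_insertion_with_target_site_duplication(self):
        sample, result = resolve_simulated("line_insertion", seed=2)
        res = next(r for r in result.resolutions.values() if r.label == "LINE")
        assert res.line.target_site_duplication == 16
        assert res.line.insertion_distance == -16

    def test_transduction_attributed_to_source(self):
        sample, result = resolve_simulated("line_insertion", seed=2,
                                           params={"transduction": True})
        res = next(r for r in result.resolutions.values() if r.label == "LINE")
        assert res.line.transductions
        source, offset = res.line.transductions[0]
        assert 0 < offset <= 5_000

    def test_known_source_translocation_resolves_line(self, karyotype,
                                                      uniform_profile,
                                                      junction_factory, config):
        kb = KnowledgeBase(line_sources=[("chr2", 5_000_000, 5_006_000)])
        j = junction_factory("t", "chr1", 1_000_000, 1, "chr2", 5_001_000, -1)
        res = run_sample([j], uniform_profile(), karyotype, kb=kb)
        assert res.resolutions[0].label == "LINE"
        assert any(s.startswith("known") for s in res.resolutions[0].line.sources)


class TestPseudogene:
    def test_full_sixteen_exon_insertion(self):
        sample, result = resolve_simulated("pseudogene_insertion", seed=5)
        res = next(r for r in result.resolutions.values() if r.label == "PSEUDOGENE")
        assert res.pseudogene.exon_count == 16
        assert res.pseudogene.introns_matched == 15

    def test_partial_match_not_resolved(self, gene_model, junction_factory, config):
        """Deletions matching only 3 of 15 introns stay unresolved."""
        tx = gene_model["PGD1"].canonical()
        exons = sorted(tx.exons, key=lambda e: e.start)
        dels = []
        for k in range(3):
            dels.append(junction_factory(
                f"d{k}", "chr4", exons[k].end, 1, "chr4", exons[k + 1].start, -1))
        assert detect_pseudogene(dels, gene_model, 5, config) is None

    def test_off_splice_boundary_no_match(self, gene_model, junction_factory, config):
        tx = gene_model["PGD1"].canonical()
        exons = sorted(tx.exons, key=lambda e: e.start)
        dels = [junction_factory(f"d{k}", "chr4", exons[k].end + 300, 1,
                                 "chr4", exons[k + 1].start + 300, -1)
                for k in range(len(exons) - 1)]
        assert detect_pseudogene(dels, gene_model, 5, config) is None


class TestAmplification:
    def _classify(self, sample):
        return run_sample(sample.junctions, sample.profile, sample.karyotype,
                          sample.gene_model, sample.knowledgebase)

    def test_ecdna_triangle_called(self):
        sample, result = resolve_simulated("ecdna", seed=3)
        res = next(r for r in result.resolutions.values()
                   if r.label == "DOUBLE_MINUTE")
        assert res.mechanism == "ecDNA"
        assert res.ecdna.loop_jcn == pytest.approx(23)
        assert res.ecdna.closure == pytest.approx(1.0)

    def test_bfb_ladder_not_ecdna_and_bound_exact(self):
        """Four foldbacks: the foldback-explained amplification bound is
        2^4 x base CN and the cluster is BFB-like, not a double minute."""
        sample, result = resolve_simulated("bfb", seed=3, params={"n_cycles": 4})
        res = next(r for r in result.resolutions.values() if r.label == "COMPLEX")
        assert res.mechanism == "BFB-like"
        assert res.ecdna.foldback_count == 4
        assert res.ecdna.foldback_bound == pytest.approx(2 ** 4 * 2)
        assert not res.ecdna.is_ecdna

    def test_low_jcn_loop_rejected(self):
        sample, result = resolve_simulated("ecdna", seed=3, params={"copies": 3})
        assert not any(r.label == "DOUBLE_MINUTE" for r in result.resolutions.values())

    def test_high_amplification_threshold(self, junction_factory, uniform_profile,
                                          karyotype, config):
        from svweave.annotate import annotate_sample as ann_fn
        from svweave.classify import EcdnaCall
        low = junction_factory("a", "chr1", 1_000_000, 1, "chr2", 2_000_000, -1,
                               jcn=7.9)
        ann = ann_fn([low], karyotype, uniform_profile(), KnowledgeBase(), config)
        assert annotate_amplification_mechanism([low], EcdnaCall(False), ann,
                                                config) == "none"
        high = junction_factory("b", "chr1", 1_000_000, 1, "chr2", 2_000_000, -1,
                                jcn=8.0)
        ann = ann_fn([high], karyotype, uniform_profile(), KnowledgeBase(), config)
        assert annotate_amplification_mechanism([high], EcdnaCall(False), ann,
                                                config) == "linear-unexplained"
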