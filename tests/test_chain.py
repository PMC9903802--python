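"""Chaining: facing-pair enumeration, greedy link allocation, consistency."""

import pytest

from svweave.annotate import annotate_sample
from svweave.chain import (
    allocate_links,
    build_chains,
    check_chain_consistency,
    closure_score,
    detect_closed_chains,
    enumerate_all_maximal_pairings,
    enumerate_facing_pairs,
)
from svweave.config import Config
from svweave.genome_model import (
    CopyNumberProfile,
    CopyNumberSegment,
    KnowledgeBase,
)
from svweave.simulate import EventSpec, simulate_sample


def run_chaining(junctions, profile, karyotype, cfg=None):
    cfg = cfg or Config()
    ann = annotate_sample(junctions, karyotype, profile, KnowledgeBase(), cfg)
    cands = enumerate_facing_pairs(junctions, profile, ann, cfg)
    return ann, cands, allocate_links(junctions, cands, profile, karyotype, cfg)


class TestFacingPairs:
    def test_facing_pair_is_candidate(self, karyotype, uniform_profile,
                                      junction_factory, config):
        a = junction_factory("a", "chr1", 1_000_000, -1, "chr2", 5_000_000, 1)
        b = junction_factory("b", "chr1", 1_002_000, 1, "chr2", 8_000_000, 1)
        cands = enumerate_facing_pairs([a, b], uniform_profile(), None, config)
        chr1 = [c for c in cands if c.chromosome == "chr1"]
        assert len(chr1) == 1 and chr1[0].distance == 2_000

    def test_homozygous_deletion_blocks_traversal(self, karyotype, junction_factory,
                                                  config):
        segs = [CopyNumberSegment("chr1", 1, 1_500_000, 2, 1),
                CopyNumberSegment("chr1", 1_500_000, 1_600_000, 0, 0),
                CopyNumberSegment("chr1", 1_600_000, 50_000_001, 2, 1)]
        profile = CopyNumberProfile(segs)
        a = junction_factory("a", "chr1", 1_000_000, -1, "chr2", 5_000_000, 1)
        b = junction_factory("b", "chr1", 2_000_000, 1, "chr2", 8_000_000, 1)
        cands = enumerate_facing_pairs([a, b], profile, None, config)
        assert not [c for c in cands if c.chromosome == "chr1"]

    def test_intervening_breakend_flagged_non_adjacent(self, karyotype,
                                                       uniform_profile,
                                                       junction_factory, config):
        a = junction_factory("a", "chr1", 1_000_000, -1, "chr2", 5_000_000, 1)
        m = junction_factory("m", "chr1", 1_500_000, 1, "chr2", 6_000_000, 1)
        b = junction_factory("b", "chr1", 2_000_000, 1, "chr2", 8_000_000, 1)
        cands = enumerate_facing_pairs([a, m, b], uniform_profile(), None, config)
        wide = next(c for c in cands if c.key == ("a_a", "b_a"))
        assert not wide.adjacent


class TestAllocation:
    def test_reciprocal_translocation_two_derivatives(self, karyotype, config):
        """The only consistent pairing leaves each junction as its own open
        derivative chromosome: the breakends are back to back, so no facing
        traversal exists between them."""
        sample = simulate_sample([EventSpec("recip_trl")], seed=4)
        ann, cands, chains = run_chaining(sample.junctions, sample.profile,
                                          sample.karyotype, config)
        assert len(chains) == 2
        assert all(not ch.closed and len(ch.junction_ids) == 1 for ch in chains)

    def test_synthetic_deletion_single_chain_through_shard(self, karyotype, config):
        sample = simulate_sample([EventSpec("shard_del")], seed=4)
        ann, cands, chains = run_chaining(sample.junctions, sample.profile,
                                          sample.karyotype, config)
        assert len(chains) == 1
        ch = chains[0]
        assert len(ch.junction_ids) == 2 and len(ch.links) == 1 and not ch.closed

    def test_ecdna_triangle_closes(self, karyotype, config):
        sample = simulate_sample([EventSpec("ecdna", {"copies": 23})], seed=4)
        ann, cands, chains = run_chaining(sample.junctions, sample.profile,
                                          sample.karyotype, config)
        closed = [ch for ch in chains if ch.closed]
        assert len(closed) == 1
        assert closed[0].jcn == pytest.approx(23)
        assert len(closed[0].links) == 3

    def test_low_jcn_loop_not_closed(self, karyotype, uniform_profile,
                                     junction_factory, config):
        """A duplication-like pair that could close must stay open below the
        ecDNA copy-number floor (no centromere-less chromosome)."""
        a = junction_factory("a", "chr1", 1_000_000, 1, "chr1", 1_200_000, -1)
        b = junction_factory("b", "chr1", 1_050_000, -1, "chr1", 1_150_000, 1)
        ann, cands, chains = run_chaining([a, b], uniform_profile(3, 1),
                                          karyotype, config)
        assert all(not ch.closed for ch in chains)

    def test_trans_phased_pair_never_linked(self, karyotype, uniform_profile,
                                            junction_factory, config):
        a = junction_factory("a", "chr1", 1_000_000, -1, "chr2", 5_000_000, 1,
                             asm1=["x"])
        b = junction_factory("b", "chr1", 1_000_300, 1, "chr2", 8_000_000, 1,
                             asm1=["y"])
        ann, cands, chains = run_chaining([a, b], uniform_profile(), karyotype, config)
        assert all(not ch.links for ch in chains)

    def test_determinism(self, karyotype, config):
        sample = simulate_sample([EventSpec("chromothripsis", {"n_breaks": 12})], seed=8)
        results = []
        for _ in range(2):
            _, _, chains = run_chaining(sample.junctions, sample.profile,
                                        sample.karyotype, config)
            results.append([(ch.junction_ids, [ln.key for ln in ch.links])
                            for ch in chains])
        assert results[0] == results[1]


class TestConsistencyCheck:
    def test_over_allocation_detected(self, uniform_profile, junction_factory):
        a = junction_factory("a", "chr1", 1_000_000, -1, "chr2", 5_000_000, 1, jcn=3,
                             jcn_low=3, jcn_high=3)
        b = junction_factory("b", "chr1", 1_002_000, 1, "chr2", 8_000_000, 1, jcn=3,
                             jcn_low=3, jcn_high=3)
        from svweave.chain import ChainLink
        link = ChainLink(a.start, b.start, "a", "b", 2000, allocated_jcn=3.0)
        chains = build_chains([a, b], [link])
        residuals = check_chain_consistency(chains, uniform_profile(2, 1), 0.01)
        assert residuals and residuals[0].allocated == pytest.approx(3.0)

    def test_simulated_chains_never_over_allocate(self, config):
        """Copy conservation on simulated data: allocation stays within the
        total CN at every traversed base (tolerance 0.01)."""
        for kind in ("recip_trl", "shard_dup", "ecdna", "chromothripsis"):
            sample = simulate_sample([EventSpec(kind)], seed=13)
            _, _, chains = run_chaining(sample.junctions, sample.profile,
                                        sample.karyotype, config)
            assert check_chain_consistency(chains, sample.profile, 0.01) == []

    def test_closed_chain_jcn_disagreement_reported(self, uniform_profile,
                                                    junction_factory):
        from svweave.chain import Chain
        a = junction_factory("a", "chr1", 10, 1, "chr1", 20, -1, jcn=10,
                             jcn_low=9.5, jcn_high=10.5)
        b = junction_factory("b", "chr1", 30, 1, "chr1", 40, -1, jcn=20,
                             jcn_low=19.5, jcn_high=20.5)
        ch = Chain(0, ["a", "b"], [], closed=True, jcn=10)
        residuals = check_chain_consistency([ch], uniform_profile(), 0.01, [a, b])
        assert any(r.chromosome == "closed-chain" for r in residuals)


class TestClosureScore:
    def test_pure_loop_scores_one(self, config):
        sample = simulate_sample([EventSpec("ecdna")], seed=4)
        _, _, chains = run_chaining(sample.junctions, sample.profile,
                                    sample.karyotype, config)
        (chain, score), = detect_closed_chains(chains, sample.junctions)
        assert score == pytest.approx(1.0)

    def test_excursion_reduces_score(self, junction_factory):
        """Loop at JCN 23 with a JCN-1 excursion junction scores 23/24."""
        from svweave.chain import Chain, ChainLink
        # two-segment circle over [1.0M,1.4M] and [1.6M,2.0M]
        j1 = junction_factory("a", "chr1", 1_400_000, 1, "chr1", 1_600_000, -1,
                              jcn=23)
        j2 = junction_factory("b", "chr1", 2_000_000, 1, "chr1", 1_000_000, -1,
                              jcn=23)
        excursion = junction_factory("x", "chr1", 1_200_000, 1, "chr2", 9_000_000, -1,
                                     jcn=1)
        links = [ChainLink(j2.end, j1.start, "b", "a", 400_000, allocated_jcn=23),
                 ChainLink(j1.end, j2.start, "a", "b", 400_000, allocated_jcn=23)]
        chain = Chain(0, ["a", "b"], links, closed=True, jcn=23)
        score = closure_score(chain, [j1, j2, excursion])
        assert score == pytest.approx(23 / 24)


class TestExhaustiveOracle:
    def test_greedy_output_in_oracle_set(self, config):
        """For small clusters the greedy pairing is always one of the maximal
        consistent pairings found by brute force, and matches exactly when
        that set is a singleton."""
        kinds = ["recip_trl", "recip_dup", "shard_del", "shard_dup", "recip_inv"]
        checked = 0
        for i, kind in enumerate(kinds * 4):
            sample = simulate_sample([EventSpec(kind)], seed=100 + i)
            ann = annotate_sample(sample.junctions, sample.karyotype, sample.profile,
                                  sample.knowledgebase, config)
            cands = enumerate_facing_pairs(sample.junctions, sample.profile, ann, config)
            chains = allocate_links(sample.junctions, cands, sample.profile,
                                    sample.karyotype, config)
            got = frozenset(ln.key for ch in chains for ln in ch.links)
            oracle = enumerate_all_maximal_pairings(sample.junctions, sample.profile,
                                                    ann, config)
            assert got in oracle
            if len(oracle) == 1:
                assert got == next(iter(oracle))
            checked += 1
        assert checked == 20
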