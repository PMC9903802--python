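"""Truth-recovery studies on simulated genomes.

Each function scripts events with the simulator, runs the full
interpretation pipeline, and measures how well the inferred events match the
scripted truth.  These studies are the package's central integration
harness: the test suite asserts on their outputs and the reproduction script
reports them.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Optional

import numpy as np

from .annotate import annotate_sample
from .chain import (
    allocate_links,
    enumerate_all_maximal_pairings,
    enumerate_facing_pairs,
)
from .config import Config
from .gene_impact import (
    annotate_breakend_genes,
    call_disruptions_and_homozygous,
    poisson_upper_tail,
    test_homdisruption_enrichment,
)
from .genome_model import (
    Breakend,
    CopyNumberProfile,
    CopyNumberSegment,
    Junction,
    Karyotype,
    KnowledgeBase,
    validate_bp_consistency,
)
from .pipeline import run_sample
from .simulate import (
    ALL_EVENT_KINDS,
    EventSpec,
    SimulatedSample,
    simulate_enrichment_cohort,
    simulate_sample,
    toy_gene_model,
)

__all__ = [
    "shatter_ratio_study",
    "event_recovery_study",
    "consistency_study",
    "chaining_oracle_study",
    "ecdna_bfb_study",
    "enrichment_study",
    "fusion_toy_study",
    "homdisruption_toy_study",
    "line_pseudogene_study",
]


def _plurality_label(sample: SimulatedSample, result, event) -> Optional[str]:
    votes: Counter = Counter()
    for jid in event.junction_ids:
        cl = result.cluster_of(jid)
        if cl is not None:
            votes[cl.id] += 1
    if not votes:
        return None
    return result.resolutions[votes.most_common(1)[0][0]].label


def shatter_ratio_study(n_events: int = 300, n_breaks: int = 30, seed: int = 0) -> dict:
    """Orientation-class ratios of junctions in COMPLEX clusters across
    simulated chromothripsis events (random shatter predicts DEL:DUP:INV of
    1:1:2)."""
    counts: Counter = Counter()
    for i in range(n_events):
        sample = simulate_sample([EventSpec("chromothripsis", {"n_breaks": n_breaks})],
                                 seed=seed * 1_000_003 % (2**31 - 1) + i)
        result = run_sample(sample.junctions, sample.profile, sample.karyotype,
                            sample.gene_model, sample.knowledgebase)
        by_id = {j.id: j for j in sample.junctions}
        for cl in result.clusters:
            if result.resolutions[cl.id].label == "COMPLEX":
                for jid in cl.junction_ids:
                    counts[by_id[jid].sv_type] += 1
    return {
        "n_events": n_events,
        "n_junctions": sum(counts.values()),
        "del_to_inv_ratio": counts["DEL"] / counts["INV"],
        "dup_to_inv_ratio": counts["DUP"] / counts["INV"],
    }


def event_recovery_study(n_events: int = 500, events_per_sample: int = 4,
                         seed: int = 0) -> dict:
    """Resolved-type recovery across all scripted event classes."""
    matched = total = simple_as_complex = cross_merged_samples = n_samples = 0
    k = 0
    while total < n_events:
        kinds = [ALL_EVENT_KINDS[(k + i) % len(ALL_EVENT_KINDS)]
                 for i in range(events_per_sample)]
        k += events_per_sample
        sample = simulate_sample([EventSpec(kind) for kind in kinds],
                                 seed=seed * 999_983 % (2**31 - 1) + n_samples)
        result = run_sample(sample.junctions, sample.profile, sample.karyotype,
                            sample.gene_model, sample.knowledgebase)
        n_samples += 1
        owner: dict[int, int] = {}
        merged = False
        for ei, ev in enumerate(sample.truth):
            for jid in ev.junction_ids:
                cl = result.cluster_of(jid)
                if cl is not None:
                    if owner.setdefault(cl.id, ei) != ei:
                        merged = True
        cross_merged_samples += merged
        for ev in sample.truth:
            if total >= n_events:
                break
            total += 1
            label = _plurality_label(sample, result, ev)
            matched += label == ev.expected_label
            if ev.kind in ("simple_del", "simple_dup") and label == "COMPLEX":
                simple_as_complex += 1
    return {
        "n_events": total,
        "recovery_rate": matched / total,
        "simple_labeled_complex": simple_as_complex,
        "cross_merge_fraction": cross_merged_samples / n_samples,
    }


def consistency_study(n_samples: int = 24, seed: int = 0) -> dict:
    """Every emitted callset must pass base-pair consistency at 0.01; a
    deliberately injected one-copy error must always be detected."""
    passed = detected = 0
    for i in range(n_samples):
        kinds = [ALL_EVENT_KINDS[i % len(ALL_EVENT_KINDS)],
                 ALL_EVENT_KINDS[(i + 5) % len(ALL_EVENT_KINDS)]]
        sample = simulate_sample([EventSpec(kind) for kind in kinds],
                                 seed=seed * 7_919 % (2**31 - 1) + i)
        passed += validate_bp_consistency(sample.junctions, sample.profile,
                                          0.01).consistent
        # inject a 1-copy error into the widest segment of a rearranged
        # chromosome (one with internal boundaries to check against)
        segs = list(sample.profile.all_segments())
        multi = {c for c in sample.profile.by_chromosome
                 if len(sample.profile.by_chromosome[c]) > 1}
        candidates = [k for k, s in enumerate(segs) if s.chromosome in multi]
        widest = max(candidates, key=lambda k: segs[k].end - segs[k].start)
        broken = [
            CopyNumberSegment(s.chromosome, s.start, s.end,
                              s.cn_total + (1.0 if k == widest else 0.0), s.cn_minor)
            for k, s in enumerate(segs)
        ]
        report = validate_bp_consistency(sample.junctions,
                                         CopyNumberProfile(broken), 0.01)
        detected += not report.consistent
    return {
        "n_samples": n_samples,
        "consistent_fraction": passed / n_samples,
        "injected_error_detection_rate": detected / n_samples,
    }


def chaining_oracle_study(n_clusters: int = 100, seed: int = 0) -> dict:
    """Greedy chaining audited against the exhaustive enumerator of maximal
    consistent pairings on small clusters."""
    cfg = Config()
    kinds = ["recip_trl", "recip_dup", "shard_del", "shard_dup", "recip_inv",
             "ecdna", "line_insertion"]
    tested = in_oracle = singleton = exact = 0
    i = 0
    while tested < n_clusters:
        sample = simulate_sample([EventSpec(kinds[i % len(kinds)])],
                                 seed=seed * 104_729 % (2**31 - 1) + i)
        i += 1
        result = run_sample(sample.junctions, sample.profile, sample.karyotype,
                            sample.gene_model, sample.knowledgebase)
        by_id = {j.id: j for j in sample.junctions}
        for cl in result.clusters:
            if not (2 <= len(cl.junction_ids) <= 6) or tested >= n_clusters:
                continue
            members = [by_id[j] for j in cl.junction_ids]
            cands = enumerate_facing_pairs(members, sample.profile,
                                           result.annotations, cfg)
            chains = allocate_links(members, cands, sample.profile,
                                    sample.karyotype, cfg)
            got = frozenset(ln.key for ch in chains for ln in ch.links)
            oracle = enumerate_all_maximal_pairings(members, sample.profile,
                                                    result.annotations, cfg)
            tested += 1
            in_oracle += got in oracle
            if len(oracle) == 1:
                singleton += 1
                exact += got == next(iter(oracle))
    return {
        "n_clusters": tested,
        "oracle_membership_rate": in_oracle / tested,
        "singleton_clusters": singleton,
        "singleton_exact_rate": exact / singleton if singleton else 1.0,
    }


def ecdna_bfb_study(n_each: int = 100, seed: int = 0) -> dict:
    """Discrimination between circular (ecDNA) and linear foldback-driven
    (BFB) amplification, plus the exact foldback-explained bound."""
    confusions = 0
    bound_ok = 0
    for i in range(n_each):
        sample = simulate_sample([EventSpec("ecdna")],
                                 seed=seed * 15_485_863 % (2**31 - 1) + i)
        result = run_sample(sample.junctions, sample.profile, sample.karyotype,
                            sample.gene_model, sample.knowledgebase)
        if not any(r.label == "DOUBLE_MINUTE" and r.mechanism == "ecDNA"
                   for r in result.resolutions.values()):
            confusions += 1
    for i in range(n_each):
        sample = simulate_sample([EventSpec("bfb", {"n_cycles": 4})],
                                 seed=seed * 32_452_843 % (2**31 - 1) + i)
        result = run_sample(sample.junctions, sample.profile, sample.karyotype,
                            sample.gene_model, sample.knowledgebase)
        bfb_like = False
        for r in result.resolutions.values():
            if r.label == "DOUBLE_MINUTE":
                confusions += 1
            if r.mechanism == "BFB-like":
                bfb_like = True
                if r.ecdna is not None and r.ecdna.foldback_bound == 2 ** 4 * 2:
                    bound_ok += 1
        if not bfb_like:
            confusions += 1
    return {
        "n_each": n_each,
        "confusion_rate": confusions / (2 * n_each),
        "foldback_bound_exact_rate": bound_ok / n_each,
    }


def enrichment_study(n_seeds: int = 50, seed: int = 0) -> dict:
    """Poisson upper-tail p-values against an independent series-summation
    oracle, and recovery of a ten-fold enriched gene at FDR < 0.1."""

    def series_tail(k: int, lam: float, terms: int = 600) -> float:
        if k <= 0:
            return 1.0
        term = math.exp(-lam + k * math.log(lam) - math.lgamma(k + 1))
        total = 0.0
        for i in range(k, k + terms):
            total += term
            term *= lam / (i + 1)
        return total

    max_err = 0.0
    rng = np.random.default_rng(seed)
    for _ in range(200):
        lam = float(rng.uniform(0.01, 20))
        k = int(rng.integers(1, 40))
        max_err = max(max_err, abs(poisson_upper_tail(k, lam) - series_tail(k, lam)))

    hits = 0
    for i in range(n_seeds):
        counts, lengths = simulate_enrichment_cohort(
            seed=seed * 49_979_687 % (2**31 - 1) + i)
        res = test_homdisruption_enrichment(counts, lengths)
        hits += any(r.gene == "G000" and r.significant for r in res)
    return {
        "n_seeds": n_seeds,
        "p_value_max_abs_error": max_err,
        "enriched_gene_recovery_rate": hits / n_seeds,
    }


def _uniform_profile(karyotype: Karyotype, cn: float = 2.0, minor: float = 1.0
                     ) -> CopyNumberProfile:
    return CopyNumberProfile([CopyNumberSegment(c.name, 1, c.length, cn, minor)
                              for c in karyotype.chromosomes.values()])


def fusion_toy_study() -> dict:
    """Constructed two-gene fusions: direct in-frame, phase-mismatched, and
    chained through a 500-base shard."""
    karyotype = Karyotype.toy()
    gm = toy_gene_model()
    kb = KnowledgeBase(known_fusion_pairs=[("FUS5", "FUS3")])

    def trl(jid, c1, p1, o1, c2, p2, o2):
        return Junction(jid, Breakend(jid + "_a", c1, p1, o1),
                        Breakend(jid + "_b", c2, p2, o2))

    out = {}
    direct = trl("f", "chr1", 8_002_000, 1, "chr2", 8_048_000, -1)
    res = run_sample([direct], _uniform_profile(karyotype), karyotype, gm, kb)
    f = next(x for x in res.fusions if x.gene_5p == "FUS5" and x.gene_3p == "FUS3")
    out["direct_in_frame"] = int(f.in_frame and f.reportable)
    out["direct_links"] = f.links

    mism = trl("m", "chr1", 8_002_000, 1, "chr2", 8_007_000, -1)
    res = run_sample([mism], _uniform_profile(karyotype), karyotype, gm, kb)
    f = next(x for x in res.fusions if x.gene_3p == "FUS3")
    out["phase_mismatch_in_frame"] = int(f.in_frame)

    hop1 = trl("h1", "chr1", 8_002_000, 1, "chr3", 1_000_000, -1)
    hop2 = trl("h2", "chr3", 1_000_500, 1, "chr2", 8_048_000, -1)
    res = run_sample([hop1, hop2], _uniform_profile(karyotype), karyotype, gm, kb)
    f = next(x for x in res.fusions if x.gene_5p == "FUS5" and x.gene_3p == "FUS3")
    out["chained_links"] = f.links
    out["chained_in_frame"] = int(f.in_frame)
    return out


def homdisruption_toy_study() -> dict:
    """Reciprocal translocation through a CN-2 tumor suppressor: both
    derivatives truncate the gene, yet exonic copy number stays 2."""
    karyotype = Karyotype.toy()
    gm = toy_gene_model()
    cfg = Config()

    def trl(jid, c1, p1, o1, c2, p2, o2):
        return Junction(jid, Breakend(jid + "_a", c1, p1, o1),
                        Breakend(jid + "_b", c2, p2, o2))

    a = trl("r1", "chr3", 30_018_000, 1, "chr4", 10_000_000, -1)
    b = trl("r2", "chr3", 30_018_001, -1, "chr4", 10_000_001, 1)
    profile = _uniform_profile(karyotype)
    anns = annotate_breakend_genes([a, b], gm, cfg)
    (recip,) = call_disruptions_and_homozygous([a, b], profile, anns, gm,
                                               ["TSG1"], cfg)
    anns1 = annotate_breakend_genes([a], gm, cfg)
    (single,) = call_disruptions_and_homozygous([a], profile, anns1, gm,
                                                ["TSG1"], cfg)
    return {
        "reciprocal_min_exonic_cn": recip.min_exonic_cn,
        "reciprocal_undisrupted_copies": recip.undisrupted_copies,
        "reciprocal_homozygous": int(recip.homozygous),
        "single_trl_homozygous": int(single.homozygous),
    }


def line_pseudogene_study(seed: int = 0) -> dict:
    """A LINE insertion with a 16-base target-site duplication and a
    16-exon processed-pseudogene insertion, both recovered end to end."""
    out = {}
    sample = simulate_sample([EventSpec("line_insertion")],
                             seed=seed * 2_147_483_029 % (2**31 - 1) + 1)
    result = run_sample(sample.junctions, sample.profile, sample.karyotype,
                        sample.gene_model, sample.knowledgebase)
    line = next(r for r in result.resolutions.values() if r.label == "LINE")
    out["line_resolved"] = 1
    out["target_site_duplication"] = line.line.target_site_duplication

    sample = simulate_sample([EventSpec("pseudogene_insertion")],
                             seed=seed * 2_147_483_029 % (2**31 - 1) + 2)
    result = run_sample(sample.junctions, sample.profile, sample.karyotype,
                        sample.gene_model, sample.knowledgebase)
    pg = next(r for r in result.resolutions.values() if r.label == "PSEUDOGENE")
    out["pseudogene_resolved"] = 1
    out["pseudogene_introns_matched"] = pg.pseudogene.introns_matched
    out["pseudogene_exons"] = pg.pseudogene.exon_count
    return out
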