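"""End-to-end orchestration: annotate -> cluster -> chain -> classify ->
gene impact, plus the tabular outputs."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import annotate as _annotate
from . import chain as _chain
from . import classify as _classify
from . import cluster as _cluster
from . import gene_impact as _gi
from .config import Config
from .genome_model import (
    ConsistencyReport,
    CopyNumberProfile,
    GeneModelCollection,
    Junction,
    Karyotype,
    KnowledgeBase,
    validate_bp_consistency,
)

__all__ = ["PipelineResult", "run_sample", "write_tables"]

OUTPUT_TABLES = ("svs_annotated.tsv", "clusters.tsv", "links.tsv", "chains.tsv",
                 "fusions.tsv", "disruptions.tsv", "drivers.tsv", "ig_events.tsv")


@dataclass
class PipelineResult:
    junctions: list[Junction]
    profile: CopyNumberProfile
    annotations: _annotate.AnnotationSet
    clusters: list[_cluster.Cluster]
    chains_by_cluster: dict[int, list[_chain.Chain]]
    resolutions: dict[int, _classify.ResolvedCluster]
    consistency: ConsistencyReport
    gene_annotations: dict = field(default_factory=dict)
    fusions: list = field(default_factory=list)
    disruptions: list = field(default_factory=list)
    drivers: list = field(default_factory=list)
    ig_events: list = field(default_factory=list)
    exon_rearrangements: list = field(default_factory=list)

    def cluster_of(self, junction_id: str) -> Optional[_cluster.Cluster]:
        for cl in self.clusters:
            if junction_id in cl.junction_ids:
                return cl
        return None


def run_sample(junctions: Sequence[Junction], profile: CopyNumberProfile,
               karyotype: Karyotype, gene_model: Optional[GeneModelCollection] = None,
               kb: Optional[KnowledgeBase] = None,
               config: Optional[Config] = None) -> PipelineResult:
    """Run the full interpretation pipeline on one sample in memory."""
    cfg = config or Config()
    kb = kb or KnowledgeBase()
    junctions = list(junctions)
    consistency = validate_bp_consistency(junctions, profile, cfg.consistency_tolerance)
    ann = _annotate.annotate_sample(junctions, karyotype, profile, kb, cfg)
    clusters = _cluster.cluster_all(junctions, ann, cfg)
    by_id = {j.id: j for j in junctions}

    chains_by_cluster: dict[int, list[_chain.Chain]] = {}
    for cl in clusters:
        members = [by_id[j] for j in cl.junction_ids]
        if len(members) >= 2:
            cands = _chain.enumerate_facing_pairs(members, profile, ann, cfg)
            chains = _chain.allocate_links(members, cands, profile, karyotype, cfg)
        else:
            chains = _chain.build_chains(members, [], karyotype)
        chains_by_cluster[cl.id] = chains

    resolutions = _classify.classify_sample(clusters, junctions, chains_by_cluster,
                                            profile, ann, gene_model, kb, cfg)

    result = PipelineResult(junctions, profile, ann, clusters, chains_by_cluster,
                            resolutions, consistency)
    if gene_model is not None:
        result.gene_annotations = _gi.annotate_breakend_genes(junctions, gene_model, cfg)
        all_chains = [ch for chs in chains_by_cluster.values() for ch in chs]
        result.fusions = _gi.call_fusions(all_chains, junctions, result.gene_annotations,
                                          gene_model, kb, cfg)
        result.disruptions = _gi.call_disruptions_and_homozygous(
            junctions, profile, result.gene_annotations, gene_model,
            kb.driver_panel or None, cfg)
        result.ig_events = _gi.call_ig_rearrangements(junctions, kb, gene_model, cfg)
        result.exon_rearrangements = _gi.call_exon_rearrangements(junctions, gene_model, kb)
        result.drivers = _gi.match_drivers(clusters, junctions, profile, gene_model, kb,
                                           disruptions=result.disruptions, config=cfg)
    return result


def write_tables(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    def table(name: str, header: list[str], rows: list[list]) -> None:
        p = out / name
        with open(p, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for r in rows:
                fh.write("\t".join(str(x) for x in r) + "\n")
        paths.append(p)

    cluster_of = {}
    for cl in result.clusters:
        for jid in cl.junction_ids:
            cluster_of[jid] = cl.id

    rows = []
    for j in result.junctions:
        for b in j.breakends:
            a = result.annotations.of(b)
            rows.append([j.id, b.id, b.chromosome, b.position, b.orientation, j.sv_type,
                         f"{j.jcn:g}", a.arm, int(a.is_foldback), int(a.flanks_loh),
                         int(a.in_fragile_site), a.line_source, cluster_of.get(j.id, -1)])
    table("svs_annotated.tsv",
          ["junction", "breakend", "chromosome", "position", "orientation", "sv_type",
           "jcn", "arm", "is_foldback", "flanks_loh", "in_fragile_site", "line_source",
           "cluster"], rows)

    rows = []
    for cl in result.clusters:
        res = result.resolutions[cl.id]
        rules = ",".join(sorted({r for r, _, _ in cl.rules})) or "."
        rows.append([cl.id, len(cl.junction_ids), rules, res.label,
                     len(res.shards), res.mechanism])
    table("clusters.tsv", ["cluster", "n_junctions", "rules", "resolved_type",
                           "n_shards", "amplification_mechanism"], rows)

    rows = []
    for cid, chains in sorted(result.chains_by_cluster.items()):
        for ch in chains:
            for i, ln in enumerate(ch.links):
                rows.append([cid, ch.id, i, ln.breakend_a.id, ln.breakend_b.id,
                             ln.chromosome, ln.interval[0], ln.interval[1],
                             f"{ln.allocated_jcn:g}"])
    table("links.tsv", ["cluster", "chain", "link", "breakend_a", "breakend_b",
                        "chromosome", "start", "end", "allocated_jcn"], rows)

    rows = []
    for cid, chains in sorted(result.chains_by_cluster.items()):
        for ch in chains:
            rows.append([cid, ch.id, int(ch.closed), f"{ch.jcn:g}",
                         len(ch.junction_ids), int(ch.spans_centromere)])
    table("chains.tsv", ["cluster", "chain", "closed", "jcn", "n_junctions",
                         "spans_centromere"], rows)

    table("fusions.tsv",
          ["gene_5p", "transcript_5p", "breakend_5p", "gene_3p", "transcript_3p",
           "breakend_3p", "links", "in_frame", "match", "reportable"],
          [[f.gene_5p, f.transcript_5p, f.breakend_5p, f.gene_3p, f.transcript_3p,
            f.breakend_3p, f.links, int(f.in_frame), f.match, int(f.reportable)]
           for f in result.fusions])

    table("disruptions.tsv",
          ["gene", "transcript", "n_disruptive", "disruptive_jcn", "min_exonic_cn",
           "undisrupted_copies", "homozygous"],
          [[d.gene, d.transcript, d.n_disruptive_junctions, f"{d.disruptive_jcn:g}",
            f"{d.min_exonic_cn:g}", f"{d.undisrupted_copies:g}", int(d.homozygous)]
           for d in result.disruptions])

    table("drivers.tsv", ["gene", "driver_type", "clusters"],
          [[m.gene, m.driver_type, ",".join(map(str, m.cluster_ids)) or "."]
           for m in result.drivers])

    table("ig_events.tsv", ["region", "ig_breakend", "partner_breakend", "oncogene"],
          [[e.region, e.ig_breakend, e.partner_breakend, e.oncogene]
           for e in result.ig_events])
    return paths
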