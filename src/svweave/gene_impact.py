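"""Gene-level consequences of rearrangements.

Breakends are annotated against transcripts (context, coding phase,
disruptiveness); derivative chains are walked to call fusions — including
chained fusions spanning several junctions — by pairing a promoter-retaining
5' context with a correctly oriented 3' context whose splice phases match;
disruptions are aggregated into homozygous-disruption calls when no intact
copy of a transcript survives although every exonic base keeps copy number;
immunoglobulin-enhancer rearrangements and driver-to-cluster links are
matched against the knowledgebase; and cohort-scale homozygous-disruption
counts are tested for per-gene enrichment with an upper-tail Poisson test
under Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy import stats

from .chain import Chain, ChainLink
from .cluster import Cluster
from .config import Config
from .genome_model import (
    Breakend,
    CopyNumberProfile,
    Gene,
    GeneModelCollection,
    Junction,
    KnowledgeBase,
    Transcript,
)

__all__ = [
    "BreakendGeneAnnotation",
    "FusionCall",
    "DisruptionCall",
    "ExonRearrangement",
    "IgEvent",
    "DriverMatch",
    "EnrichmentResult",
    "annotate_breakend_genes",
    "call_fusions",
    "call_disruptions_and_homozygous",
    "call_exon_rearrangements",
    "call_ig_rearrangements",
    "match_drivers",
    "test_homdisruption_enrichment",
    "poisson_upper_tail",
]


@dataclass
class BreakendGeneAnnotation:
    breakend_id: str
    gene: str
    transcript: str
    context: str            # upstream | intronic | exonic
    index: int              # exon/intron ordinal in transcript orientation (1-based)
    phase: int              # coding phase at the break (-1 outside coding)
    disruptive: bool


@dataclass
class FusionCall:
    gene_5p: str
    transcript_5p: str
    breakend_5p: str
    gene_3p: str
    transcript_3p: str
    breakend_3p: str
    links: int
    in_frame: bool
    match: str              # known_pair | promiscuous_5p | promiscuous_3p | none
    reportable: bool
    readthrough_like: bool = False


@dataclass
class DisruptionCall:
    gene: str
    transcript: str
    disruptive_jcn: float
    n_disruptive_junctions: int
    min_exonic_cn: float
    undisrupted_copies: float
    homozygous: bool


@dataclass(frozen=True)
class IgEvent:
    region: str
    ig_breakend: str
    partner_breakend: str
    oncogene: str


@dataclass
class DriverMatch:
    gene: str
    driver_type: str        # AMP | DEL | LOH | HOM_DISRUPTION
    cluster_ids: list[int] = field(default_factory=list)


@dataclass
class EnrichmentResult:
    gene: str
    observed: int
    expected: float
    p: float
    q: float
    significant: bool


# ---------------------------------------------------------------------------
# transcript context
# ---------------------------------------------------------------------------

def _tx_limits(tx: Transcript, strand: str) -> tuple[int, int]:
    lo, hi = tx.genomic_span()
    return (lo, hi)


def _locate(tx: Transcript, strand: str, position: int) -> Optional[tuple[str, int]]:
    """(context, ordinal) within the transcript body, in transcript
    orientation; None if outside."""
    for k, exon in enumerate(tx.exons, start=1):
        if exon.start <= position <= exon.end:
            return ("exonic", k)
    for k in range(len(tx.exons) - 1):
        a, b = tx.exons[k], tx.exons[k + 1]
        lo, hi = (a.end, b.start) if strand == "+" else (b.end, a.start)
        if lo < position < hi:
            return ("intronic", k + 1)
    return None


def _phase_at(tx: Transcript, strand: str, context: str, ordinal: int, position: int) -> int:
    if context == "intronic":
        return tx.exons[ordinal - 1].end_phase
    if context == "exonic":
        if not tx.is_coding:
            return -1
        cum = 0
        for exon in tx.exons:
            s, e = exon.start, exon.end
            cs = max(s, tx.coding_start)
            ce = min(e, tx.coding_end)
            if s <= position <= e:
                if position < cs or position > ce:
                    return -1
                off = (position - cs + 1) if strand == "+" else (ce - position + 1)
                return (cum + off) % 3
            if ce >= cs:
                cum += ce - cs + 1
        return -1
    return -1


def annotate_breakend_genes(junctions: Sequence[Junction],
                            gene_model: GeneModelCollection,
                            config: Optional[Config] = None
                            ) -> dict[str, list[BreakendGeneAnnotation]]:
    """One annotation per (breakend, overlapped transcript), including the
    upstream promoter window.

    A breakend is non-disruptive for a transcript when its junction re-joins
    entirely within one intron (both breakends in the same intron), leaving
    the exon chain intact, or when it only touches the upstream window.
    """
    cfg = config or Config()
    out: dict[str, list[BreakendGeneAnnotation]] = {}
    for j in junctions:
        for b in j.breakends:
            anns: list[BreakendGeneAnnotation] = []
            window = max(cfg.fusion_promoter_window, cfg.disruption_upstream_window)
            for gene in gene_model.overlapping(b.chromosome, b.position - window,
                                               b.position + window):
                for tx in gene.transcripts:
                    lo, hi = _tx_limits(tx, gene.strand)
                    loc = _locate(tx, gene.strand, b.position)
                    if loc is None:
                        if gene.strand == "+" and lo - cfg.fusion_promoter_window <= b.position < lo:
                            anns.append(BreakendGeneAnnotation(
                                b.id, gene.name, tx.id, "upstream", 0, -1, False))
                        elif gene.strand == "-" and hi < b.position <= hi + cfg.fusion_promoter_window:
                            anns.append(BreakendGeneAnnotation(
                                b.id, gene.name, tx.id, "upstream", 0, -1, False))
                        continue
                    context, ordinal = loc
                    phase = _phase_at(tx, gene.strand, context, ordinal, b.position)
                    disruptive = True
                    if (j.end is not None and context == "intronic"
                            and j.start.chromosome == j.end.chromosome):
                        other = j.end if b.id == j.start.id else j.start
                        oloc = _locate(tx, gene.strand, other.position)
                        if oloc == loc:
                            disruptive = False   # junction confined to one intron
                    anns.append(BreakendGeneAnnotation(
                        b.id, gene.name, tx.id, context, ordinal, phase, disruptive))
            if anns:
                out[b.id] = anns
    return out


# ---------------------------------------------------------------------------
# fusions
# ---------------------------------------------------------------------------

def _viable_5p(ann: BreakendGeneAnnotation, gene: Gene, b: Breakend) -> bool:
    want = 1 if gene.strand == "+" else -1
    return ann.context in ("upstream", "intronic", "exonic") and b.orientation == want


def _viable_3p(ann: BreakendGeneAnnotation, gene: Gene, b: Breakend) -> bool:
    want = -1 if gene.strand == "+" else 1
    return ann.context in ("intronic", "exonic") and b.orientation == want


def _match_class(a: str, b: str, kb: KnowledgeBase) -> str:
    if (a, b) in kb.known_fusion_pairs:
        return "known_pair"
    if a in kb.promiscuous_5p:
        return "promiscuous_5p"
    if b in kb.promiscuous_3p:
        return "promiscuous_3p"
    return "none"


def call_fusions(chains: Sequence[Chain], junctions: Sequence[Junction],
                 gene_annotations: dict[str, list[BreakendGeneAnnotation]],
                 gene_model: GeneModelCollection, kb: KnowledgeBase,
                 config: Optional[Config] = None) -> list[FusionCall]:
    """Walk every derivative chain looking for splice-compatible 5'/3'
    partner contexts, possibly across multiple links (chained fusions).

    A candidate is rejected when an intervening chain breakend truncates
    either partner transcript before its retained end.  In-frame requires
    equal exit/entry phases (non-coding -1 only fuses -1).  Same-chromosome
    promiscuous candidates closer than the readthrough distance are flagged
    and not reported.
    """
    cfg = config or Config()
    by_id = {j.id: j for j in junctions}
    bnd_by_id: dict[str, Breakend] = {}
    junction_of: dict[str, str] = {}
    for j in junctions:
        for b in j.breakends:
            bnd_by_id[b.id] = b
            junction_of[b.id] = j.id

    calls: list[FusionCall] = []
    seen: set[tuple] = set()
    for chain in chains:
        link_at: dict[str, ChainLink] = {}
        for ln in chain.links:
            link_at[ln.breakend_a.id] = ln
            link_at[ln.breakend_b.id] = ln

        def truncated(b: Breakend, gene: Gene, tx: Transcript, side: str) -> bool:
            """Does a link attached to this breakend lead back into the
            retained portion of the transcript, severing it?"""
            ln = link_at.get(b.id)
            if ln is None:
                return False
            other = ln.breakend_b if ln.breakend_a.id == b.id else ln.breakend_a
            lo, hi = tx.genomic_span()
            if other.chromosome != gene.chromosome:
                return False
            retain_high = (b.orientation == -1)
            if side == "5p":
                retained = (b.position, hi) if retain_high else (lo, b.position)
            else:
                retained = (b.position, hi) if retain_high else (lo, b.position)
            return retained[0] <= other.position <= retained[1]

        for j_id in chain.junction_ids:
            j = by_id[j_id]
            if j.end is None:
                continue
            for e5, first_other in ((j.start, j.end), (j.end, j.start)):
                for a5 in gene_annotations.get(e5.id, []):
                    gene5 = gene_model[a5.gene]
                    if not _viable_5p(a5, gene5, e5):
                        continue
                    if truncated(e5, gene5, gene5.canonical(), "5p"):
                        continue
                    # walk forward across junctions and links
                    landing = first_other
                    links = 1
                    while links <= cfg.max_fusion_links:
                        for a3 in gene_annotations.get(landing.id, []):
                            gene3 = gene_model[a3.gene]
                            if not _viable_3p(a3, gene3, landing):
                                continue
                            if a3.gene == a5.gene and landing.id == e5.id:
                                continue
                            if truncated(landing, gene3, gene3.canonical(), "3p"):
                                continue
                            in_frame = (a5.phase == a3.phase)
                            match = _match_class(a5.gene, a3.gene, kb)
                            readthrough = (
                                match.startswith("promiscuous")
                                and gene5.chromosome == gene3.chromosome
                                and abs(gene5.span()[0] - gene3.span()[0]) < cfg.readthrough_distance
                            )
                            key = (a5.gene, a3.gene, e5.id, landing.id)
                            if key in seen:
                                continue
                            seen.add(key)
                            calls.append(FusionCall(
                                a5.gene, a5.transcript, e5.id,
                                a3.gene, a3.transcript, landing.id,
                                links, in_frame, match,
                                reportable=match != "none" and not readthrough,
                                readthrough_like=readthrough))
                        ln = link_at.get(landing.id)
                        if ln is None:
                            break
                        nxt = ln.breakend_b if ln.breakend_a.id == landing.id else ln.breakend_a
                        j2 = by_id[junction_of[nxt.id]]
                        if j2.end is None:
                            break
                        landing = j2.end if j2.start.id == nxt.id else j2.start
                        links += 1
    return calls


# ---------------------------------------------------------------------------
# disruptions
# ---------------------------------------------------------------------------

def call_disruptions_and_homozygous(junctions: Sequence[Junction],
                                    profile: CopyNumberProfile,
                                    gene_annotations: dict[str, list[BreakendGeneAnnotation]],
                                    gene_model: GeneModelCollection,
                                    panel: Optional[Sequence[str]] = None,
                                    config: Optional[Config] = None
                                    ) -> list[DisruptionCall]:
    """Per-gene disruption bookkeeping.

    Undisrupted copies = (minimum exonic total CN) minus the summed JCN of
    the gene's disruptive junctions, floored at zero.  A homozygous
    disruption is called when every exonic base keeps CN above the
    homozygous-deletion threshold yet fewer than half a copy remains
    undisrupted — e.g. a reciprocal translocation whose two derivatives each
    carry only part of the gene, or a tandem duplication overlapping an exon
    with both breakends inside the transcript when only one copy exists.
    """
    cfg = config or Config()
    by_jid = {j.id: j for j in junctions}
    junction_of = {b.id: j.id for j in junctions for b in j.breakends}

    per_tx: dict[tuple[str, str], set[str]] = {}
    for bid, anns in gene_annotations.items():
        for a in anns:
            if a.disruptive:
                per_tx.setdefault((a.gene, a.transcript), set()).add(junction_of[bid])

    calls = []
    genes = panel if panel is not None else sorted({g for g, _ in per_tx})
    for gene_name in genes:
        if gene_name not in gene_model:
            continue
        gene = gene_model[gene_name]
        tx = gene.canonical()
        jids = per_tx.get((gene_name, tx.id), set())
        if not jids:
            continue
        min_exonic = min(profile.min_cn(gene.chromosome, e.start, e.end) for e in tx.exons)
        disruptive_jcn = sum(by_jid[j].jcn for j in jids)
        undisrupted = max(0.0, min_exonic - disruptive_jcn)
        homozygous = min_exonic >= cfg.homdel_threshold and undisrupted < 0.5
        calls.append(DisruptionCall(gene_name, tx.id, disruptive_jcn, len(jids),
                                    min_exonic, undisrupted, homozygous))
    return calls


@dataclass(frozen=True)
class ExonRearrangement:
    gene: str
    transcript: str
    junction: str
    sv_type: str            # DEL | DUP
    first_exon: int
    last_exon: int
    known_pathogenic: bool


def call_exon_rearrangements(junctions: Sequence[Junction],
                             gene_model: GeneModelCollection,
                             kb: KnowledgeBase) -> list[ExonRearrangement]:
    """Intragenic deletions/duplications spanning whole exons, matched
    against the knowledgebase of known pathogenic exon ranges (e.g. exon-
    skipping deletions and internal tandem duplications of kinase genes)."""
    known = {(gene, typ): (lo, hi)
             for gene, lo, hi, typ in kb.pathogenic_exon_rearrangements}
    out = []
    for j in junctions:
        if j.sv_type not in ("DEL", "DUP") or j.end is None:
            continue
        lo_pos, hi_pos = sorted(b.position for b in j.breakends)
        for gene in gene_model.overlapping(j.start.chromosome, lo_pos, hi_pos):
            tx = gene.canonical()
            span_lo, span_hi = tx.genomic_span()
            if not (span_lo <= lo_pos and hi_pos <= span_hi):
                continue   # both breakends must be intragenic
            covered = [k for k, e in enumerate(
                sorted(tx.exons, key=lambda e: e.start), start=1)
                if lo_pos <= e.start and e.end <= hi_pos]
            if not covered:
                continue
            first, last = covered[0], covered[-1]
            if gene.strand == "-":
                n = len(tx.exons)
                first, last = n - last + 1, n - first + 1
            hit = known.get((gene.name, j.sv_type))
            pathogenic = hit is not None and hit[0] <= first and last <= hit[1]
            out.append(ExonRearrangement(gene.name, tx.id, j.id, j.sv_type,
                                         first, last, pathogenic))
    return out


# ---------------------------------------------------------------------------
# IG enhancer rearrangements and driver matching
# ---------------------------------------------------------------------------

def call_ig_rearrangements(junctions: Sequence[Junction], kb: KnowledgeBase,
                           gene_model: GeneModelCollection,
                           config: Optional[Config] = None) -> list[IgEvent]:
    """Breakend inside an immunoglobulin enhancer region with the required
    orientation whose partner lands upstream of (oriented toward) or within
    an oncogene on the driver panel."""
    cfg = config or Config()
    events = []
    for j in junctions:
        if j.end is None:
            continue
        for b, partner in ((j.start, j.end), (j.end, j.start)):
            for region in kb.ig_regions:
                if not (b.chromosome == region.chromosome
                        and region.start <= b.position <= region.end
                        and b.orientation == region.orientation):
                    continue
                for gene_name in kb.driver_panel:
                    if gene_name not in gene_model:
                        continue
                    g = gene_model[gene_name]
                    if g.chromosome != partner.chromosome:
                        continue
                    lo, hi = g.span()
                    if lo <= partner.position <= hi:
                        events.append(IgEvent(region.name, b.id, partner.id, gene_name))
                    elif g.strand == "+" and lo - cfg.fusion_promoter_window <= partner.position < lo \
                            and partner.orientation == -1:
                        events.append(IgEvent(region.name, b.id, partner.id, gene_name))
                    elif g.strand == "-" and hi < partner.position <= hi + cfg.fusion_promoter_window \
                            and partner.orientation == 1:
                        events.append(IgEvent(region.name, b.id, partner.id, gene_name))
    return events


def match_drivers(clusters: Sequence[Cluster], junctions: Sequence[Junction],
                  profile: CopyNumberProfile, gene_model: GeneModelCollection,
                  kb: KnowledgeBase,
                  drivers: Optional[Sequence[tuple[str, str]]] = None,
                  disruptions: Optional[Sequence[DisruptionCall]] = None,
                  config: Optional[Config] = None) -> list[DriverMatch]:
    """Link amplification / deletion / LOH drivers (supplied, or derived from
    the copy-number profile over panel genes) to the clusters whose junction
    breakends bound or fall within the driven gene; homozygous-disruption
    drivers are appended."""
    cfg = config or Config()
    by_jid = {j.id: j for j in junctions}
    if drivers is None:
        drivers = []
        for name in kb.driver_panel:
            if name not in gene_model:
                continue
            g = gene_model[name]
            lo, hi = g.span()
            cns = [s.cn_total for s in profile.segments(g.chromosome)
                   if s.start <= hi and s.end > lo]
            minors = [s.cn_minor for s in profile.segments(g.chromosome)
                      if s.start <= hi and s.end > lo]
            if not cns:
                continue
            if min(cns) >= 3 * cfg.ploidy:
                drivers.append((name, "AMP"))
            elif min(cns) < cfg.homdel_threshold:
                drivers.append((name, "DEL"))
            elif minors and max(minors) < cfg.loh_threshold:
                drivers.append((name, "LOH"))

    matches = []
    for gene_name, dtype in drivers:
        m = DriverMatch(gene_name, dtype)
        if gene_name in gene_model:
            g = gene_model[gene_name]
            lo, hi = g.span()
            pad = 100_000
            for cl in clusters:
                hit = any(b.chromosome == g.chromosome and lo - pad <= b.position <= hi + pad
                          for jid in cl.junction_ids for b in by_jid[jid].breakends)
                if hit:
                    m.cluster_ids.append(cl.id)
        matches.append(m)

    for d in disruptions or []:
        if d.homozygous:
            m = DriverMatch(d.gene, "HOM_DISRUPTION")
            g = gene_model[d.gene]
            lo, hi = g.span()
            for cl in clusters:
                if any(b.chromosome == g.chromosome and lo <= b.position <= hi
                       for jid in cl.junction_ids for b in by_jid[jid].breakends):
                    m.cluster_ids.append(cl.id)
            matches.append(m)
    return matches


# ---------------------------------------------------------------------------
# cohort enrichment
# ---------------------------------------------------------------------------

def poisson_upper_tail(observed: int, lam: float) -> float:
    """P(X >= observed) for X ~ Poisson(lam); 1.0 when observed is 0."""
    if observed <= 0:
        return 1.0
    return float(stats.poisson.sf(observed - 1, lam))


def test_homdisruption_enrichment(counts: dict[str, int], lengths: dict[str, float],
                                  total_gene_length: Optional[float] = None,
                                  fdr: float = 0.1) -> list[EnrichmentResult]:
    """Genome-wide enrichment of homozygous disruptions.

    The background rate is total observed events divided by the summed gene
    length; each gene's expectation is rate x length; the p-value is the
    upper Poisson tail, corrected with Benjamini-Hochberg; genes below the
    FDR threshold are flagged.
    """
    from statsmodels.stats.multitest import multipletests

    genes = sorted(lengths)
    total_obs = sum(counts.get(g, 0) for g in genes)
    total_len = total_gene_length if total_gene_length is not None else sum(
        lengths[g] for g in genes)
    rate = total_obs / total_len if total_len > 0 else 0.0
    ps = []
    for g in genes:
        lam = rate * lengths[g]
        ps.append(poisson_upper_tail(counts.get(g, 0), lam) if total_obs > 0 else 1.0)
    if ps:
        _, qs, _, _ = multipletests(ps, method="fdr_bh")
    else:
        qs = []
    out = []
    for g, p, q in zip(genes, ps, qs):
        lam = rate * lengths[g]
        out.append(EnrichmentResult(g, counts.get(g, 0), lam, float(p), float(q),
                                    bool(q < fdr)))
    return out
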