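"""Resolution of clusters into event types.

Every cluster receives exactly one label.  Dispatch order: mobile-element
(LINE) evidence, pseudogene insertion, single-junction simple events,
two-junction resolution (reciprocal inversion / translocation / duplication
or a synthetic simple event with inserted genomic shards), the ecDNA
(double-minute) heuristic, then COMPLEX for three or more junctions and
INCOMPLETE otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .annotate import AnnotationSet, has_polya_signal
from .chain import Chain, closure_score, detect_closed_chains
from .cluster import Cluster
from .config import Config
from .genome_model import (
    Breakend,
    CopyNumberProfile,
    GeneModelCollection,
    Junction,
    KnowledgeBase,
    derive_sv_type,
)

__all__ = [
    "ShardAnnotation",
    "ResolvedCluster",
    "LineResolution",
    "PseudogeneMatch",
    "EcdnaCall",
    "detect_shards",
    "synthetic_reduction",
    "resolve_two_break",
    "resolve_line_cluster",
    "detect_pseudogene",
    "detect_ecdna",
    "annotate_amplification_mechanism",
    "resolve_cluster",
    "classify_sample",
]

LABELS = {
    "DEL", "DUP", "SYNTH_DEL", "SYNTH_DUP", "SYNTH_TRL", "RECIP_INV", "RECIP_TRL",
    "RECIP_DUP", "INS", "LINE", "PSEUDOGENE", "COMPLEX", "DOUBLE_MINUTE",
    "SGL_PAIR", "INCOMPLETE", "SINGLE",
}


@dataclass(frozen=True)
class ShardAnnotation:
    chromosome: str
    start: int
    end: int
    length: int
    host_chromosome: Optional[str] = None
    host_position: Optional[int] = None


@dataclass
class LineResolution:
    sources: list[str] = field(default_factory=list)     # known/suspected source hits
    transductions: list[tuple[str, int]] = field(default_factory=list)
    insertion_distance: Optional[int] = None             # negative => TSD
    target_site_duplication: Optional[int] = None


@dataclass
class PseudogeneMatch:
    transcript: str
    exon_count: int
    introns_matched: int
    introns_total: int


@dataclass
class EcdnaCall:
    is_ecdna: bool
    loop_jcn: float = 0.0
    closure: float = 0.0
    flank_cn: float = 0.0
    foldback_bound: float = 0.0
    feed_jcn: float = 0.0
    foldback_count: int = 0


@dataclass
class ResolvedCluster:
    cluster_id: int
    label: str
    shards: list[ShardAnnotation] = field(default_factory=list)
    mechanism: str = "none"      # none | ecDNA | BFB-like | linear-unexplained
    line: Optional[LineResolution] = None
    pseudogene: Optional[PseudogeneMatch] = None
    ecdna: Optional[EcdnaCall] = None


# ---------------------------------------------------------------------------
# shards and synthetic reduction
# ---------------------------------------------------------------------------

def detect_shards(chain: Chain, junctions: Sequence[Junction],
                  config: Optional[Config] = None) -> list[ShardAnnotation]:
    """Traversed intervals shorter than the shard threshold whose flanking
    junctions both jump off the interval's chromosome (or far away on it)."""
    cfg = config or Config()
    by_id = {j.id: j for j in junctions}
    shards = []
    for ln in chain.links:
        s, e = ln.interval
        length = e - s + 1
        if length >= cfg.shard_max_length:
            continue

        def remote(jid: str, local: Breakend) -> Optional[Breakend]:
            j = by_id[jid]
            others = [b for b in j.breakends if b.id != local.id]
            return others[0] if others else None

        ra = remote(ln.junction_a, ln.breakend_a)
        rb = remote(ln.junction_b, ln.breakend_b)

        def leaves(b: Optional[Breakend]) -> bool:
            if b is None:
                return False
            if b.chromosome != ln.chromosome:
                return True
            return not (s - 10_000 <= b.position <= e + 10_000)

        if leaves(ra) and leaves(rb):
            host = ra if ra is not None else rb
            shards.append(ShardAnnotation(ln.chromosome, s, e, length,
                                          host.chromosome, host.position))
    return shards


def synthetic_reduction(chain: Chain, junctions: Sequence[Junction],
                        config: Optional[Config] = None
                        ) -> Optional[tuple[str, Optional[int], list[ShardAnnotation]]]:
    """Collapse an open chain whose every traversed interval is a shard into
    the notional simple event formed by fusing the chain's free breakends.

    Returns (sv type, length, shards) or None when the chain does not reduce.
    """
    cfg = config or Config()
    if chain.closed or len(chain.links) != len(chain.junction_ids) - 1 or not chain.links:
        return None
    shards = detect_shards(chain, junctions, cfg)
    if len(shards) != len(chain.links):
        return None
    by_id = {j.id: j for j in junctions}
    used = {b for ln in chain.links for b in ln.key}
    free = [b for jid in chain.junction_ids for b in by_id[jid].breakends
            if b.id not in used]
    if len(free) != 2:
        return None
    a, b = free
    svt = derive_sv_type(a, b)
    length = abs(a.position - b.position) if a.chromosome == b.chromosome else None
    return svt, length, shards


# ---------------------------------------------------------------------------
# two-break resolution
# ---------------------------------------------------------------------------

def resolve_two_break(junctions: Sequence[Junction], chains: Sequence[Chain],
                      config: Optional[Config] = None) -> ResolvedCluster:
    """Resolve a two-junction cluster to a reciprocal or synthetic event.

    Reciprocal inversions pair a (+,+) with a (-,-) inversion crossing it;
    reciprocal translocations have opposed breakends at both shared loci;
    reciprocal duplications have breakends *facing* each other (with overlap)
    at both loci.  A chain reducing to one notional DEL/DUP/TRL through
    shard intervals is a synthetic event.  Anything else is INCOMPLETE.
    """
    cfg = config or Config()
    a, b = junctions
    out = ResolvedCluster(-1, "INCOMPLETE")

    if a.sv_type == "SGL" and b.sv_type == "SGL":
        out.label = "SGL_PAIR"
        return out

    # shard-mediated synthetic events first: a templated insertion shorter
    # than the shard threshold can mimic the reciprocal patterns below
    for ch in chains:
        if set(ch.junction_ids) == {a.id, b.id} and not ch.closed:
            red = synthetic_reduction(ch, junctions, cfg)
            if red is not None and red[0] in ("DEL", "DUP", "TRL"):
                out.label = f"SYNTH_{red[0]}"
                out.shards = red[2]
                return out

    if a.sv_type == "INV" and b.sv_type == "INV" and a.end is not None and b.end is not None:
        o_a, o_b = a.start.orientation, b.start.orientation
        if o_a != o_b and a.start.chromosome == b.start.chromosome:
            s1, e1 = sorted(x.position for x in a.breakends)
            s2, e2 = sorted(x.position for x in b.breakends)
            if s1 > s2:
                (s1, e1), (s2, e2) = (s2, e2), (s1, e1)
            if s2 <= e1:   # the two inversions overlap / cross
                out.label = "RECIP_INV"
                return out

    if a.sv_type == "TRL" and b.sv_type == "TRL" and a.end is not None and b.end is not None:
        chroms_a = {x.chromosome for x in a.breakends}
        chroms_b = {x.chromosome for x in b.breakends}
        if chroms_a == chroms_b and len(chroms_a) == 2:
            relation = []
            for chrom in sorted(chroms_a):
                x = next(be for be in a.breakends if be.chromosome == chrom)
                y = next(be for be in b.breakends if be.chromosome == chrom)
                if x.orientation == y.orientation:
                    relation.append("same")
                else:
                    minus, plus = (x, y) if x.orientation == -1 else (y, x)
                    relation.append("facing" if minus.position < plus.position else "opposed")
            if relation == ["facing", "facing"]:
                out.label = "RECIP_DUP"
                return out
            if relation == ["opposed", "opposed"]:
                out.label = "RECIP_TRL"
                return out

    return out


# ---------------------------------------------------------------------------
# LINE and pseudogene
# ---------------------------------------------------------------------------

def resolve_line_cluster(junctions: Sequence[Junction], annotations: AnnotationSet,
                         kb: KnowledgeBase, config: Optional[Config] = None
                         ) -> Optional[LineResolution]:
    """Resolve a mobile-element insertion cluster.

    Fires when a breakend maps into a known or suspected LINE source, or when
    insertion-site breakends carry poly-A insert sequence or a LINE repeat
    class.  Partnered transductions are remote intervals within the
    transduction window downstream of a source; the insertion-site breakend
    overlap is reported (negative distance = target-site duplication).
    """
    cfg = config or Config()
    evidence = False
    res = LineResolution()
    for j in junctions:
        for b in j.breakends:
            src = annotations.of(b).line_source
            if src != "none":
                evidence = True
                res.sources.append(f"{src}:{b.chromosome}:{b.position}")
            if has_polya_signal(b.insert_sequence, cfg.polya_min_length, cfg.polya_purity):
                evidence = True
            if (b.repeat_class or "").upper() in ("LINE", "L1", "POLYA"):
                evidence = True
    if not evidence:
        return None

    # transductions: junction side within the window downstream of a source
    for j in junctions:
        if j.end is None:
            continue
        for b in j.breakends:
            for chrom, s, e in kb.line_sources:
                if b.chromosome == chrom and e < b.position <= e + cfg.transduction_distance:
                    res.transductions.append((f"{chrom}:{s}-{e}", b.position - e))

    # insertion-site distance: nearest facing pair among cluster breakends
    bnds = [b for j in junctions for b in j.breakends]
    best = None
    for i, x in enumerate(bnds):
        for y in bnds[i + 1:]:
            if x.chromosome != y.chromosome or x.orientation == y.orientation:
                continue
            if any(x.chromosome == c and s <= x.position <= e for c, s, e in kb.line_sources):
                continue
            plus, minus = (x, y) if x.orientation == 1 else (y, x)
            d = minus.position - plus.position - 1
            if abs(d) <= 1_000 and (best is None or abs(d) < abs(best)):
                best = d
    if best is not None:
        res.insertion_distance = best
        if best < 0:
            res.target_site_duplication = -best
    return res


def detect_pseudogene(junctions: Sequence[Junction], gene_model: GeneModelCollection,
                      tolerance: int = 5, config: Optional[Config] = None
                      ) -> Optional[PseudogeneMatch]:
    """Match the cluster's deletions against the intron boundaries of a
    single transcript.

    A processed-transcript insertion appears as one deletion per intron with
    breakends at the splice boundaries.  Resolution requires at least
    ``pseudogene_min_introns`` matched and at least ``pseudogene_min_fraction``
    of the transcript's introns matched; flanking integration junctions
    (TRL/SGL) are tolerated.  Partial matches return None.
    """
    cfg = config or Config()
    dels = [j for j in junctions if j.sv_type == "DEL"]
    if len(dels) < cfg.pseudogene_min_introns:
        return None
    chrom = dels[0].start.chromosome
    lo = min(b.position for j in dels for b in j.breakends)
    hi = max(b.position for j in dels for b in j.breakends)
    best: Optional[PseudogeneMatch] = None
    for gene in gene_model.overlapping(chrom, lo, hi):
        for tx in gene.transcripts:
            exons = sorted(tx.exons, key=lambda e: e.start)
            introns = [(exons[i].end, exons[i + 1].start) for i in range(len(exons) - 1)]
            if not introns:
                continue
            matched = set()
            all_dels_match = True
            for j in dels:
                plus = next(b for b in j.breakends if b.orientation == 1)
                minus = next(b for b in j.breakends if b.orientation == -1)
                hit = None
                for k, (donor, acceptor) in enumerate(introns):
                    if (abs(plus.position - donor) <= tolerance
                            and abs(minus.position - acceptor) <= tolerance):
                        hit = k
                        break
                if hit is None:
                    all_dels_match = False
                else:
                    matched.add(hit)
            if not all_dels_match:
                continue
            if (len(matched) >= cfg.pseudogene_min_introns
                    and len(matched) / len(introns) >= cfg.pseudogene_min_fraction):
                cand = PseudogeneMatch(tx.id, len(exons), len(matched), len(introns))
                if best is None or cand.introns_matched > best.introns_matched:
                    best = cand
    return best


# ---------------------------------------------------------------------------
# amplification mechanisms
# ---------------------------------------------------------------------------

def _foldback_count(junctions: Sequence[Junction], annotations: AnnotationSet) -> int:
    pairs = set()
    for j in junctions:
        for b in j.breakends:
            ann = annotations.of(b)
            if ann.is_foldback and ann.foldback_partner is not None:
                pairs.add(frozenset((b.id, ann.foldback_partner)))
    return len(pairs)


def detect_ecdna(junctions: Sequence[Junction], chains: Sequence[Chain],
                 profile: CopyNumberProfile, annotations: AnnotationSet,
                 config: Optional[Config] = None) -> EcdnaCall:
    """ecDNA (double-minute) heuristic.

    Requires a closed or predominantly closed chain whose junction copy
    number is at least ``ecdna_jcn_min``, at least ``ecdna_adjacency_ratio``
    times the copy number immediately flanking the loop segments, and larger
    than what foldback amplification (``2^n_foldbacks × base CN``) plus
    non-loop junctions feeding the region could produce.
    """
    cfg = config or Config()
    call = EcdnaCall(False)
    closed = detect_closed_chains(chains, junctions)
    n_fold = _foldback_count(junctions, annotations)
    call.foldback_count = n_fold
    for chain, score in sorted(closed, key=lambda t: -t[1]):
        if score < cfg.ecdna_closure_min:
            continue
        footprint = [(ln.chromosome, *ln.interval) for ln in chain.links]
        flanks = []
        for c, s, e in footprint:
            for p in (s - 1, e + 1):
                segs = profile.segments(c)
                if segs and segs[0].start <= p < segs[-1].end:
                    if not any(c2 == c and s2 <= p <= e2 for c2, s2, e2 in footprint):
                        flanks.append(profile.cn_at(c, p))
        flank_cn = max(flanks) if flanks else cfg.ploidy
        base_cn = min(flanks) if flanks else cfg.ploidy
        loop_ids = set(chain.junction_ids)
        feed = sum(j.jcn for j in junctions if j.id not in loop_ids
                   and any(b.chromosome == c and s <= b.position <= e
                           for b in j.breakends for c, s, e in footprint))
        bound = (2 ** n_fold) * base_cn
        call.loop_jcn = chain.jcn
        call.closure = score
        call.flank_cn = flank_cn
        call.foldback_bound = bound
        call.feed_jcn = feed
        if (chain.jcn >= cfg.ecdna_jcn_min
                and chain.jcn >= cfg.ecdna_adjacency_ratio * flank_cn
                and chain.jcn > bound + feed):
            call.is_ecdna = True
            return call
    if not closed:
        # still report the foldback-explained bound for BFB-style clusters
        base = cfg.ploidy
        call.foldback_bound = (2 ** n_fold) * base
    return call


def annotate_amplification_mechanism(junctions: Sequence[Junction], ecdna: EcdnaCall,
                                     annotations: AnnotationSet,
                                     config: Optional[Config] = None) -> str:
    """Mechanism label for high-amplification clusters (max JCN >= threshold):
    ecDNA when the loop heuristic fired, BFB-like with at least one foldback,
    otherwise linear-unexplained; low-amplification clusters get 'none'."""
    cfg = config or Config()
    max_jcn = max((j.jcn for j in junctions), default=0.0)
    if max_jcn < cfg.high_amp_jcn:
        return "none"
    if ecdna.is_ecdna:
        return "ecDNA"
    if _foldback_count(junctions, annotations) >= 1:
        return "BFB-like"
    return "linear-unexplained"


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def resolve_cluster(cluster: Cluster, junctions: Sequence[Junction],
                    chains: Sequence[Chain], profile: CopyNumberProfile,
                    annotations: AnnotationSet, gene_model: Optional[GeneModelCollection],
                    kb: KnowledgeBase, config: Optional[Config] = None) -> ResolvedCluster:
    """Total dispatch: every cluster receives exactly one label."""
    cfg = config or Config()
    out = ResolvedCluster(cluster.id, "INCOMPLETE")

    line = resolve_line_cluster(junctions, annotations, kb, cfg)
    if line is not None:
        out.label = "LINE"
        out.line = line
        return out

    if gene_model is not None:
        pg = detect_pseudogene(junctions, gene_model, cfg.pseudogene_tolerance, cfg)
        if pg is not None:
            out.label = "PSEUDOGENE"
            out.pseudogene = pg
            return out

    for ch in chains:
        out.shards.extend(detect_shards(ch, junctions, cfg))

    if len(junctions) == 1:
        j = junctions[0]
        if j.sv_type == "SGL":
            out.label = "SINGLE"
        elif j.sv_type == "DUP" and j.insert_sequence and (j.length or 0) < 100:
            out.label = "INS"
        elif j.sv_type in ("DEL", "DUP"):
            out.label = j.sv_type
        else:
            out.label = "INCOMPLETE"
        return out

    ecdna = detect_ecdna(junctions, chains, profile, annotations, cfg)
    out.ecdna = ecdna
    out.mechanism = annotate_amplification_mechanism(junctions, ecdna, annotations, cfg)

    if len(junctions) == 2:
        two = resolve_two_break(junctions, chains, cfg)
        if two.label != "INCOMPLETE":
            out.label = two.label
            out.shards = two.shards or out.shards
            return out
        if ecdna.is_ecdna:
            out.label = "DOUBLE_MINUTE"
            return out
        out.label = "INCOMPLETE"
        return out

    if ecdna.is_ecdna:
        out.label = "DOUBLE_MINUTE"
        return out

    if len(junctions) >= 3:
        # a larger cluster may still reduce to one synthetic simple event
        for ch in chains:
            if set(ch.junction_ids) == {j.id for j in junctions}:
                red = synthetic_reduction(ch, junctions, cfg)
                if red is not None and red[0] in ("DEL", "DUP", "TRL"):
                    out.label = f"SYNTH_{red[0]}"
                    out.shards = red[2]
                    return out
        out.label = "COMPLEX"
        return out

    return out


def classify_sample(clusters: Sequence[Cluster], junctions: Sequence[Junction],
                    chains_by_cluster: dict[int, list[Chain]],
                    profile: CopyNumberProfile, annotations: AnnotationSet,
                    gene_model: Optional[GeneModelCollection], kb: KnowledgeBase,
                    config: Optional[Config] = None) -> dict[int, ResolvedCluster]:
    """Resolve every cluster; also writes the label back onto the cluster."""
    by_id = {j.id: j for j in junctions}
    out = {}
    for cl in clusters:
        members = [by_id[j] for j in cl.junction_ids]
        res = resolve_cluster(cl, members, chains_by_cluster.get(cl.id, []),
                              profile, annotations, gene_model, kb, config)
        cl.resolved_type = res.label
        cl.is_line = res.label == "LINE" or cl.is_line
        out[cl.id] = res
    return out
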