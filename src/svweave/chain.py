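"""Derivative-chromosome prediction by iterative breakend linking.

Within each cluster, facing breakend pairs (a ``-1`` breakend below a ``+1``
breakend on one chromosome) are candidate traversals of the intervening
segment.  A greedy loop repeatedly links the highest-priority viable pair
under allele-specific copy-number constraints: a traversal may never
allocate more copies than the interval has left, may not cross a homozygous
deletion, and trans-phased pairs are never linked (they live on different
derivative copies).  Chains that would close into a loop are only allowed
when the loop's junction copy number is high enough to qualify as candidate
extrachromosomal DNA — derivative chromosomes without a centromere are
otherwise not permitted.

The module also provides an exhaustive enumerator of all maximal consistent
pairings for small clusters; it is a brute-force reference used to audit the
greedy algorithm.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .annotate import AnnotationSet
from .config import Config
from .genome_model import Breakend, CopyNumberProfile, Junction

__all__ = [
    "ChainLink",
    "Chain",
    "enumerate_facing_pairs",
    "allocate_links",
    "build_chains",
    "check_chain_consistency",
    "detect_closed_chains",
    "closure_score",
    "enumerate_all_maximal_pairings",
]


@dataclass
class ChainLink:
    """A traversal from a ``-1`` breakend up to a facing ``+1`` breakend."""
    breakend_a: Breakend          # orientation -1, lower position
    breakend_b: Breakend          # orientation +1, higher position
    junction_a: str
    junction_b: str
    distance: int
    phase: str = "unknown"
    adjacent: bool = True         # no other cluster breakend strictly between
    allocated_jcn: float = 0.0

    @property
    def chromosome(self) -> str:
        return self.breakend_a.chromosome

    @property
    def interval(self) -> tuple[int, int]:
        return self.breakend_a.position, self.breakend_b.position

    @property
    def key(self) -> tuple[str, str]:
        return (self.breakend_a.id, self.breakend_b.id)


@dataclass
class Chain:
    id: int
    junction_ids: list[str]
    links: list[ChainLink]
    closed: bool
    jcn: float
    spans_centromere: bool = False


def enumerate_facing_pairs(junctions: Sequence[Junction], profile: CopyNumberProfile,
                           annotations: Optional[AnnotationSet] = None,
                           config: Optional[Config] = None) -> list[ChainLink]:
    """All candidate links between facing breakends of different junctions.

    A pair is excluded when the traversed interval crosses a homozygous
    deletion (total CN below threshold anywhere disqualifies).  Candidates
    carry their distance, phase label and adjacency flag.
    """
    cfg = config or Config()
    bnds = [(b, j) for j in junctions for b in j.breakends]
    positions = sorted((b.chromosome, b.position) for b, _ in bnds)
    candidates: list[ChainLink] = []
    for (a, ja), (b, jb) in itertools.combinations(bnds, 2):
        if ja.id == jb.id or a.chromosome != b.chromosome:
            continue
        if {a.orientation, b.orientation} != {1, -1}:
            continue
        lo, hi = (a, b) if a.orientation == -1 else (b, a)
        if lo.position > hi.position:
            continue  # overlapping ends face away from the interval
        if profile.min_cn(lo.chromosome, lo.position, hi.position) < cfg.homdel_threshold:
            continue
        phase = "unknown"
        if annotations is not None:
            pp = annotations.phase_of(a.id, b.id)
            if pp is not None:
                phase = pp.label
            elif set(a.assembly_ids) & set(b.assembly_ids):
                phase = "cis"
        between = any(c == lo.chromosome and lo.position < p < hi.position
                      for c, p in positions if True)
        ja_id, jb_id = (ja.id, jb.id) if a.orientation == -1 else (jb.id, ja.id)
        candidates.append(ChainLink(lo, hi, ja_id, jb_id,
                                    hi.position - lo.position, phase, not between))
    return candidates


def _jcn_compatible(a: Junction, b: Junction) -> bool:
    """Junctions may link when their JCN windows overlap, or when one JCN is
    close to an integer multiple of the other (foldback replication)."""
    if a.jcn_low <= b.jcn_high and b.jcn_low <= a.jcn_high:
        return True
    lo, hi = sorted((max(a.jcn, 1e-9), max(b.jcn, 1e-9)))
    ratio = hi / lo
    return abs(ratio - round(ratio)) <= 0.25 and round(ratio) >= 2


class _Allocator:
    """Tracks per-interval copy allocation of accepted links."""

    def __init__(self, profile: CopyNumberProfile):
        self.profile = profile
        self.taken: list[tuple[str, int, int, float]] = []

    def available(self, chromosome: str, start: int, end: int) -> float:
        points = {start, end}
        for s in self.profile.segments(chromosome):
            if start <= s.start <= end:
                points.add(s.start)
        for c, a, b, _ in self.taken:
            if c == chromosome:
                for p in (a, b):
                    if start <= p <= end:
                        points.add(p)
        worst = float("inf")
        for p in sorted(points):
            cn = self.profile.cn_at(chromosome, p)
            used = sum(v for c, a, b, v in self.taken if c == chromosome and a <= p <= b)
            worst = min(worst, cn - used)
        return worst

    def allocate(self, link: ChainLink) -> None:
        a, b = link.interval
        self.taken.append((link.chromosome, a, b, link.allocated_jcn))


def allocate_links(junctions: Sequence[Junction], candidates: Sequence[ChainLink],
                   profile: CopyNumberProfile, karyotype=None,
                   config: Optional[Config] = None) -> list[Chain]:
    """Greedy link allocation.

    Priority cascade per iteration: (1) cis-assembled pairs; (2) pairs that
    are the only viable partner for both breakends; (3) adjacent pairs;
    (4) shorter traversed distance; (5) higher minimum JCN; ties broken by
    genomic coordinate.  A chain may only close on itself when its JCN meets
    the ecDNA candidate minimum.  Unresolvable clusters yield partial chains.
    """
    cfg = config or Config()
    by_id = {j.id: j for j in junctions}
    linked: set[str] = set()               # breakend ids already used
    chain_end: dict[str, int] = {}         # open breakend id -> component id
    comp_of: dict[str, int] = {}           # junction id -> component id
    comp_members: dict[int, set[str]] = {}
    accepted: list[ChainLink] = []
    alloc = _Allocator(profile)
    next_comp = itertools.count()

    def endpoints(jid: str) -> list[str]:
        return [b.id for b in by_id[jid].breakends]

    def comp_jcn(cid: int) -> float:
        return min(by_id[j].jcn for j in comp_members[cid])

    def viable(link: ChainLink) -> bool:
        if link.phase == "trans":
            return False
        a, b = link.breakend_a.id, link.breakend_b.id
        if a in linked or b in linked:
            return False
        ja, jb = by_id[link.junction_a], by_id[link.junction_b]
        if not _jcn_compatible(ja, jb):
            return False
        ca, cb = comp_of.get(ja.id), comp_of.get(jb.id)
        if ca is not None and ca == cb:
            # closing link: permitted only for ecDNA-grade loops
            if comp_jcn(ca) < cfg.ecdna_jcn_min:
                return False
        want = min(ja.jcn, jb.jcn)
        s, e = link.interval
        return alloc.available(link.chromosome, s, e) + 1e-9 >= want

    while True:
        pool = [c for c in candidates if viable(c)]
        if not pool:
            break
        partner_count: dict[str, int] = {}
        for c in pool:
            partner_count[c.breakend_a.id] = partner_count.get(c.breakend_a.id, 0) + 1
            partner_count[c.breakend_b.id] = partner_count.get(c.breakend_b.id, 0) + 1

        def priority(c: ChainLink):
            forced = partner_count[c.breakend_a.id] == 1 and partner_count[c.breakend_b.id] == 1
            min_jcn = min(by_id[c.junction_a].jcn, by_id[c.junction_b].jcn)
            return (c.phase != "cis", not forced, not c.adjacent, c.distance,
                    -min_jcn, c.chromosome, c.interval)

        best = min(pool, key=priority)
        ja, jb = by_id[best.junction_a], by_id[best.junction_b]
        link = replace(best, allocated_jcn=min(ja.jcn, jb.jcn))
        alloc.allocate(link)
        accepted.append(link)
        linked.update(link.key)
        ca, cb = comp_of.get(ja.id), comp_of.get(jb.id)
        if ca is None and cb is None:
            cid = next(next_comp)
            comp_members[cid] = {ja.id, jb.id}
        elif ca is None:
            cid = cb
            comp_members[cid].add(ja.id)
        elif cb is None:
            cid = ca
            comp_members[cid].add(jb.id)
        elif ca != cb:
            cid = ca
            comp_members[cid] |= comp_members.pop(cb)
        else:
            cid = ca
        for j in comp_members[cid]:
            comp_of[j] = cid

    return build_chains(junctions, accepted, karyotype)


def build_chains(junctions: Sequence[Junction], links: Sequence[ChainLink],
                 karyotype=None) -> list[Chain]:
    """Assemble chains (paths / cycles over junctions connected by links);
    unlinked junctions become single-junction open chains."""
    by_id = {j.id: j for j in junctions}
    adj: dict[str, list[ChainLink]] = {j.id: [] for j in junctions}
    for ln in links:
        adj[ln.junction_a].append(ln)
        adj[ln.junction_b].append(ln)

    seen: set[str] = set()
    chains: list[Chain] = []
    for j in junctions:
        if j.id in seen:
            continue
        # walk the component
        component = {j.id}
        frontier = [j.id]
        while frontier:
            cur = frontier.pop()
            for ln in adj[cur]:
                for nxt in (ln.junction_a, ln.junction_b):
                    if nxt not in component:
                        component.add(nxt)
                        frontier.append(nxt)
        seen |= component
        comp_links = [ln for ln in links
                      if ln.junction_a in component and ln.junction_b in component]
        # a component is closed when every member junction has both breakends
        # linked; a single breakend's missing mate is an open end, so chains
        # containing SGLs are never closed
        used = [b for ln in comp_links for b in ln.key]
        n_free = sum(1 for jid in component for b in by_id[jid].breakends
                     if b.id not in used)
        all_paired = all(by_id[jid].end is not None for jid in component)
        closed = len(component) >= 2 and n_free == 0 and all_paired
        jcn = min(by_id[jid].jcn for jid in component)
        spans_cen = False
        if karyotype is not None:
            for ln in comp_links:
                c = karyotype[ln.chromosome]
                s, e = ln.interval
                if s <= c.centromere_start and e >= c.centromere_end:
                    spans_cen = True
            for jid in component:
                arms = {(b.chromosome, karyotype.arm_of(b.chromosome, b.position))
                        for b in by_id[jid].breakends}
                chroms = {c for c, _ in arms}
                for c in chroms:
                    if {(c, "P"), (c, "Q")} <= arms:
                        spans_cen = True
        chains.append(Chain(len(chains), sorted(component), comp_links, closed,
                            jcn, spans_cen))
    return chains


@dataclass
class ChainResidual:
    chromosome: str
    position: int
    allocated: float
    cn_total: float


def check_chain_consistency(chains: Sequence[Chain], profile: CopyNumberProfile,
                            tolerance: float = 0.01,
                            junctions: Optional[Sequence[Junction]] = None,
                            ) -> list[ChainResidual]:
    """Report every traversed point where summed link allocation exceeds the
    total copy number, and closed chains whose member JCNs disagree beyond
    their uncertainty windows (reported at position -1)."""
    residuals: list[ChainResidual] = []
    links = [ln for ch in chains for ln in ch.links]
    points: dict[str, set[int]] = {}
    for ln in links:
        s, e = ln.interval
        points.setdefault(ln.chromosome, set()).update((s, e))
        for seg in profile.segments(ln.chromosome):
            if s <= seg.start <= e:
                points.setdefault(ln.chromosome, set()).add(seg.start)
    for chrom, ps in points.items():
        for p in sorted(ps):
            total = sum(ln.allocated_jcn for ln in links
                        if ln.chromosome == chrom and ln.interval[0] <= p <= ln.interval[1])
            cn = profile.cn_at(chrom, p)
            if total > cn + tolerance:
                residuals.append(ChainResidual(chrom, p, total, cn))
    if junctions is not None:
        by_id = {j.id: j for j in junctions}
        for ch in chains:
            if not ch.closed:
                continue
            lo = max(by_id[j].jcn_low for j in ch.junction_ids)
            hi = min(by_id[j].jcn_high for j in ch.junction_ids)
            if lo > hi:
                residuals.append(ChainResidual("closed-chain", -1, lo, hi))
    return residuals


def closure_score(chain: Chain, junctions: Sequence[Junction]) -> float:
    """Fraction of junction copy number in the loop relative to total
    junction copy number feeding the amplified region: the loop JCN divided
    by loop JCN plus the JCN of non-loop junctions with a breakend in the
    loop's traversed footprint."""
    if not chain.closed:
        return 0.0
    loop_ids = set(chain.junction_ids)
    footprint = [(ln.chromosome, *ln.interval) for ln in chain.links]
    excursion = 0.0
    for j in junctions:
        if j.id in loop_ids:
            continue
        if any(b.chromosome == c and s <= b.position <= e
               for b in j.breakends for c, s, e in footprint):
            excursion += j.jcn
    return chain.jcn / (chain.jcn + excursion) if chain.jcn + excursion > 0 else 0.0


def detect_closed_chains(chains: Sequence[Chain], junctions: Sequence[Junction]
                         ) -> list[tuple[Chain, float]]:
    """Closed chains with their closure scores."""
    return [(ch, closure_score(ch, junctions)) for ch in chains if ch.closed]


# ---------------------------------------------------------------------------
# exhaustive reference enumerator (small clusters)
# ---------------------------------------------------------------------------

def enumerate_all_maximal_pairings(junctions: Sequence[Junction],
                                   profile: CopyNumberProfile,
                                   annotations: Optional[AnnotationSet] = None,
                                   config: Optional[Config] = None,
                                   max_junctions: int = 6,
                                   ) -> set[frozenset[tuple[str, str]]]:
    """Brute force over all link subsets for clusters of up to
    ``max_junctions`` junctions.

    Returns every *maximal* set of disjoint viable links whose combined
    allocation respects the copy-number constraint at every traversed base
    and the closed-loop rule.  Used to audit :func:`allocate_links`: the
    greedy output must be a member of this set.
    """
    cfg = config or Config()
    if len(junctions) > max_junctions:
        raise ValueError("exhaustive enumeration limited to small clusters")
    by_id = {j.id: j for j in junctions}
    cands = [c for c in enumerate_facing_pairs(junctions, profile, annotations, cfg)
             if c.phase != "trans" and _jcn_compatible(by_id[c.junction_a], by_id[c.junction_b])]

    def feasible(subset: list[ChainLink]) -> bool:
        used: set[str] = set()
        for c in subset:
            if c.breakend_a.id in used or c.breakend_b.id in used:
                return False
            used.update(c.key)
        alloc = _Allocator(profile)
        for c in subset:
            want = min(by_id[c.junction_a].jcn, by_id[c.junction_b].jcn)
            if alloc.available(c.chromosome, *c.interval) + 1e-9 < want:
                return False
            alloc.allocate(replace(c, allocated_jcn=want))
        chains = build_chains(junctions, [
            replace(c, allocated_jcn=min(by_id[c.junction_a].jcn, by_id[c.junction_b].jcn))
            for c in subset])
        for ch in chains:
            if ch.closed and ch.jcn < cfg.ecdna_jcn_min:
                return False
        return True

    feasible_sets: list[set[tuple[str, str]]] = []
    for r in range(len(cands) + 1):
        for combo in itertools.combinations(cands, r):
            if feasible(list(combo)):
                feasible_sets.append({c.key for c in combo})

    maximal = []
    for s in feasible_sets:
        if not any(s < t for t in feasible_sets):
            maximal.append(frozenset(s))
    return set(maximal)
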