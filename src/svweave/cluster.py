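"""Grouping of junctions into rearrangement events.

An event is one or more junctions judged likely to have occurred proximately
in time.  Merging is driven by a registry of independent pairwise rules —
proximity, LOH / homozygous-deletion / high-major-allele bounding,
common arms of translocations, overlap of inversions and long DEL/DUP
variants, and same-arm foldbacks — and the final partition is the transitive
closure of the pairwise merge relation.  Junctions with mobile-element
(LINE) evidence are only ever clustered by proximity, so that LINE
translocation scatter does not contaminate complex clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .annotate import AnnotationSet
from .config import Config
from .genome_model import Junction

__all__ = [
    "Cluster",
    "cluster_all",
    "pairwise_merges",
    "rule_proximity",
    "rule_loh_bounds",
    "rule_common_arms",
    "rule_overlap_invs_longdels_dups",
    "rule_foldbacks_same_arm",
    "DEFAULT_RULES",
]


@dataclass
class Cluster:
    id: int
    junction_ids: list[str]
    rules: list[tuple[str, str, str]] = field(default_factory=list)  # (rule, jid_a, jid_b)
    resolved_type: str = ""
    is_line: bool = False

    def __len__(self) -> int:
        return len(self.junction_ids)


def _min_breakend_distance(a: Junction, b: Junction) -> Optional[int]:
    dists = [abs(x.position - y.position)
             for x in a.breakends for y in b.breakends
             if x.chromosome == y.chromosome]
    return min(dists) if dists else None


def rule_proximity(a: Junction, b: Junction, annotations: AnnotationSet,
                   config: Config) -> bool:
    """Merge when any two breakends lie on one chromosome strictly closer
    than the proximity threshold (default < 5 kb)."""
    d = _min_breakend_distance(a, b)
    return d is not None and d < config.proximity_distance


def rule_common_arms(a: Junction, b: Junction, annotations: AnnotationSet,
                     config: Config) -> bool:
    """Merge two translocations whose unordered (chromosome, arm) pairs at
    both ends are identical."""
    if a.sv_type != "TRL" or b.sv_type != "TRL":
        return False

    def arms(j: Junction) -> frozenset:
        return frozenset((x.chromosome, annotations.of(x).arm) for x in j.breakends)

    return arms(a) == arms(b) and len(arms(a)) == 2


def rule_overlap_invs_longdels_dups(a: Junction, b: Junction, annotations: AnnotationSet,
                                    config: Config) -> bool:
    """Merge inversions (any length) and long DEL/DUP variants whose position
    intervals cross-overlap (neither nested in the other)."""

    def qualifies(j: Junction) -> bool:
        if j.sv_type == "INV":
            return True
        if j.sv_type in ("DEL", "DUP"):
            return (j.length or 0) >= config.long_variant_threshold
        return False

    if not (qualifies(a) and qualifies(b)):
        return False
    if a.start.chromosome != b.start.chromosome:
        return False
    (s1, e1) = sorted(x.position for x in a.breakends)
    (s2, e2) = sorted(x.position for x in b.breakends)
    if s1 > s2 or (s1 == s2 and e1 > e2):
        s1, e1, s2, e2 = s2, e2, s1, e1
    return s1 < s2 < e1 < e2


def rule_foldbacks_same_arm(a: Junction, b: Junction, annotations: AnnotationSet,
                            config: Config) -> bool:
    """Merge any two junctions carrying foldback breakends on one
    (chromosome, arm)."""

    def foldback_arms(j: Junction) -> set:
        return {(x.chromosome, annotations.of(x).arm)
                for x in j.breakends if annotations.of(x).is_foldback}

    return bool(foldback_arms(a) & foldback_arms(b))


PAIRWISE_RULES: dict[str, Callable] = {
    "proximity": rule_proximity,
    "common_arms": rule_common_arms,
    "overlap_long": rule_overlap_invs_longdels_dups,
    "foldbacks_same_arm": rule_foldbacks_same_arm,
}

# the five rule families enumerated for the clustering routine; the registry
# is extensible, and slots for additional rules can be registered by name
DEFAULT_RULES = ("proximity", "loh_bounds", "common_arms", "overlap_long",
                 "foldbacks_same_arm")

LINE_SAFE_RULES = {"proximity"}   # LINE junctions merge only by local rules


def rule_loh_bounds(junctions_by_id: dict[str, Junction], annotations: AnnotationSet
                    ) -> list[tuple[str, str]]:
    """Merge the two junctions owning the breakends that together delimit an
    LOH run, a homozygous deletion, or a high-major-allele region."""
    merges = []
    for run in annotations.bounded_runs:
        if run.left_breakend is None or run.right_breakend is None:
            continue
        ja = annotations.junction_of.get(run.left_breakend)
        jb = annotations.junction_of.get(run.right_breakend)
        if ja is not None and jb is not None and ja != jb:
            merges.append((ja, jb))
    return merges


def pairwise_merges(junctions: Sequence[Junction], annotations: AnnotationSet,
                    config: Optional[Config] = None,
                    enabled_rules: Sequence[str] = DEFAULT_RULES,
                    rules: Optional[Sequence[str]] = None,
                    ) -> list[tuple[str, str, str]]:
    """All (junction, junction, rule) merge edges implied by the given
    rules, with LINE gating applied."""
    cfg = config or Config()
    edges: list[tuple[str, str, str]] = []
    jlist = list(junctions)
    by_id = {j.id: j for j in jlist}
    rule_names = rules if rules is not None else enabled_rules

    def gated(rule: str, ja: str, jb: str) -> bool:
        if rule in LINE_SAFE_RULES:
            return False
        return ja in annotations.line_junctions or jb in annotations.line_junctions

    for name in rule_names:
        if name == "loh_bounds":
            for ja, jb in rule_loh_bounds(by_id, annotations):
                if not gated(name, ja, jb):
                    edges.append((ja, jb, name))
            continue
        fn = PAIRWISE_RULES[name]
        for i, a in enumerate(jlist):
            for b in jlist[i + 1:]:
                if gated(name, a.id, b.id):
                    continue
                if fn(a, b, annotations, cfg):
                    edges.append((a.id, b.id, name))
    return edges


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def cluster_all(junctions: Sequence[Junction], annotations: AnnotationSet,
                config: Optional[Config] = None,
                enabled_rules: Sequence[str] = DEFAULT_RULES) -> list[Cluster]:
    """Partition the junction set into clusters.

    The partition is the transitive closure of the pairwise rule relation;
    junctions matched by no rule remain singleton clusters.  Output order and
    ids are deterministic (by first junction appearance).

    The common-arms rule runs as a second stage: it only merges
    translocations still unclustered after the local rules, so that already
    coherent two-break events (e.g. shard insertions) are not absorbed into
    unrelated translocations that happen to touch the same arms.
    """
    cfg = config or Config()
    jlist = list(junctions)
    order = {j.id: i for i, j in enumerate(jlist)}
    local_rules = [r for r in enabled_rules if r != "common_arms"]
    edges = pairwise_merges(jlist, annotations, cfg, rules=local_rules)

    uf = _UnionFind([j.id for j in jlist])
    for ja, jb, rule in edges:
        uf.union(ja, jb)

    if "common_arms" in enabled_rules:
        stage1_size: dict[str, int] = {}
        for j in jlist:
            root = uf.find(j.id)
            stage1_size[root] = stage1_size.get(root, 0) + 1
        unresolved = {j.id for j in jlist if stage1_size[uf.find(j.id)] == 1}
        for ja, jb, rule in pairwise_merges(jlist, annotations, cfg,
                                            rules=["common_arms"]):
            if ja in unresolved and jb in unresolved:
                edges.append((ja, jb, rule))
                uf.union(ja, jb)

    groups: dict[str, list[str]] = {}
    for j in jlist:
        groups.setdefault(uf.find(j.id), []).append(j.id)

    clusters = []
    for members in sorted(groups.values(), key=lambda ms: min(order[m] for m in ms)):
        member_set = set(members)
        rules = [(rule, ja, jb) for ja, jb, rule in edges
                 if ja in member_set and jb in member_set]
        is_line = any(m in annotations.line_junctions for m in members)
        clusters.append(Cluster(len(clusters), sorted(members, key=order.get),
                                rules, is_line=is_line))
    return clusters
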