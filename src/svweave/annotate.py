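"""Per-breakend geometric and genomic annotation.

First stage of the interpretation pipeline: chromosome-arm membership,
foldback-inversion detection, LOH / homozygous-deletion / high-major-allele
run bounding, fragile-site and LINE-source flags, and cis/trans phasing of
proximate facing breakends.  Everything downstream (clustering, chaining,
classification) consumes the :class:`AnnotationSet` built here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .config import Config
from .genome_model import (
    Breakend,
    CopyNumberProfile,
    Junction,
    Karyotype,
    KnowledgeBase,
)

__all__ = [
    "BreakendAnnotation",
    "BoundedRun",
    "PhasePair",
    "AnnotationSet",
    "annotate_arms_and_geometry",
    "detect_foldbacks",
    "annotate_loh_and_allele_cn",
    "annotate_fragile_sites_and_line_sources",
    "annotate_phasing",
    "annotate_sample",
    "has_polya_signal",
]


@dataclass
class BreakendAnnotation:
    arm: str = "?"
    in_centromere: bool = False
    is_foldback: bool = False
    foldback_partner: Optional[str] = None
    flanks_loh: bool = False
    in_fragile_site: bool = False
    line_source: str = "none"            # none | known | suspected
    phase_groups: list[str] = field(default_factory=list)
    nearest_facing_distance: Optional[int] = None


@dataclass(frozen=True)
class BoundedRun:
    """A maximal run of CN segments matching a predicate, with the breakends
    that delimit it (None on a side that reaches the telomere)."""
    kind: str                  # loh | homdel | high_major
    chromosome: str
    start: int                 # half-open [start, end)
    end: int
    left_breakend: Optional[str]
    right_breakend: Optional[str]
    contained: tuple[str, ...] = ()


@dataclass(frozen=True)
class PhasePair:
    breakend_a: str
    breakend_b: str
    label: str                 # cis | trans | unknown
    distance: int              # negative => overlapping breakends (local duplication)


@dataclass
class AnnotationSet:
    breakends: dict[str, BreakendAnnotation] = field(default_factory=dict)
    bounded_runs: list[BoundedRun] = field(default_factory=list)
    phase_pairs: list[PhasePair] = field(default_factory=list)
    junction_of: dict[str, str] = field(default_factory=dict)
    line_junctions: set[str] = field(default_factory=set)

    def of(self, breakend: Breakend | str) -> BreakendAnnotation:
        key = breakend if isinstance(breakend, str) else breakend.id
        return self.breakends[key]

    def phase_of(self, id_a: str, id_b: str) -> Optional[PhasePair]:
        for p in self.phase_pairs:
            if {p.breakend_a, p.breakend_b} == {id_a, id_b}:
                return p
        return None


def has_polya_signal(sequence: str, min_length: int = 11, purity: float = 0.9) -> bool:
    """True when the sequence contains a window of ``min_length`` bases that
    is at least ``purity`` A (or T, for minus-strand insertions)."""
    if len(sequence) < min_length:
        return False
    seq = sequence.upper()
    need = purity * min_length
    for base in "AT":
        count = sum(1 for c in seq[:min_length] if c == base)
        if count >= need:
            return True
        for i in range(min_length, len(seq)):
            count += (seq[i] == base) - (seq[i - min_length] == base)
            if count >= need:
                return True
    return False


def annotate_arms_and_geometry(junctions: Sequence[Junction], karyotype: Karyotype,
                               annotations: Optional[AnnotationSet] = None) -> AnnotationSet:
    """Assign arm membership from the centromere interval and record basic
    junction geometry.  Unknown chromosomes raise."""
    ann = annotations or AnnotationSet()
    for j in junctions:
        for b in j.breakends:
            if b.chromosome not in karyotype:
                raise KeyError(f"breakend {b.id}: unknown chromosome {b.chromosome!r}")
            a = ann.breakends.setdefault(b.id, BreakendAnnotation())
            a.arm = karyotype.arm_of(b.chromosome, b.position)
            a.in_centromere = karyotype.in_centromere(b.chromosome, b.position)
            ann.junction_of[b.id] = j.id
    return ann


def detect_foldbacks(junctions: Sequence[Junction], annotations: AnnotationSet,
                     max_distance: int = 5_000) -> list[tuple[str, str]]:
    """Mark foldback inversions.

    A simple foldback is an inversion junction whose same-orientation
    breakends lie within ``max_distance``.  A chained foldback is a pair of
    equal-orientation breakends from *different* junctions within
    ``max_distance`` that share an assembly phase group.  Marking is
    symmetric.
    """
    pairs: list[tuple[str, str]] = []

    def mark(a: Breakend, b: Breakend) -> None:
        annotations.breakends[a.id].is_foldback = True
        annotations.breakends[a.id].foldback_partner = b.id
        annotations.breakends[b.id].is_foldback = True
        annotations.breakends[b.id].foldback_partner = a.id
        pairs.append((a.id, b.id))

    for j in junctions:
        if j.sv_type == "INV" and j.length is not None and j.length <= max_distance:
            mark(j.start, j.end)

    all_bnds = [b for j in junctions for b in j.breakends]
    for i, a in enumerate(all_bnds):
        for b in all_bnds[i + 1:]:
            if annotations.junction_of[a.id] == annotations.junction_of[b.id]:
                continue
            if (a.chromosome == b.chromosome and a.orientation == b.orientation
                    and abs(a.position - b.position) <= max_distance
                    and set(a.assembly_ids) & set(b.assembly_ids)):
                mark(a, b)
    return pairs


def _scan_runs(profile: CopyNumberProfile, predicate) -> list[tuple[str, int, int]]:
    runs = []
    for chrom, segs in profile.by_chromosome.items():
        start = None
        for s in segs:
            if predicate(s):
                if start is None:
                    start = s.start
                end = s.end
            else:
                if start is not None:
                    runs.append((chrom, start, end))
                    start = None
        if start is not None:
            runs.append((chrom, start, end))
    return runs


def annotate_loh_and_allele_cn(junctions: Sequence[Junction], profile: CopyNumberProfile,
                               annotations: AnnotationSet,
                               config: Optional[Config] = None) -> list[BoundedRun]:
    """Record maximal LOH (minor CN < threshold), homozygous-deletion
    (total CN < threshold) and high-major-allele (major CN >= ploidy + offset)
    runs, together with the breakends bounding each run.

    The left bound is a ``+1`` breakend whose CN transition sits at the run
    start, the right bound a ``-1`` breakend at the run end; a run reaching a
    telomere is single-sided.
    """
    cfg = config or Config()
    # a breakend's CN boundary: +1 at p changes CN at p+1, -1 at p changes at p
    at_boundary: dict[tuple[str, int], str] = {}
    positions: list[tuple[str, int, str]] = []
    for j in junctions:
        for b in j.breakends:
            boundary = b.position + 1 if b.orientation == 1 else b.position
            at_boundary.setdefault((b.chromosome, boundary), b.id)
            positions.append((b.chromosome, b.position, b.id))

    kinds = [
        ("homdel", lambda s: s.cn_total < cfg.homdel_threshold),
        ("loh", lambda s: s.cn_minor < cfg.loh_threshold and s.cn_total >= cfg.homdel_threshold),
        ("high_major", lambda s: s.cn_major >= cfg.ploidy + cfg.high_major_offset),
    ]
    runs: list[BoundedRun] = []
    for kind, pred in kinds:
        for chrom, start, end in _scan_runs(profile, pred):
            segs = profile.segments(chrom)
            at_left_telomere = start <= segs[0].start
            at_right_telomere = end >= segs[-1].end
            left = None if at_left_telomere else at_boundary.get((chrom, start))
            right = None if at_right_telomere else at_boundary.get((chrom, end))
            contained = tuple(bid for c, p, bid in positions
                              if c == chrom and start <= p < end and bid not in (left, right))
            runs.append(BoundedRun(kind, chrom, start, end, left, right, contained))
            for bid in (left, right):
                if bid is not None and kind in ("loh", "homdel"):
                    annotations.breakends[bid].flanks_loh = True
    annotations.bounded_runs.extend(runs)
    return runs


def annotate_fragile_sites_and_line_sources(junctions: Sequence[Junction],
                                            kb: KnowledgeBase,
                                            annotations: AnnotationSet,
                                            config: Optional[Config] = None) -> None:
    """Flag breakends in fragile sites and known LINE sources, infer suspected
    LINE source loci, and mark LINE-evidence junctions.

    A locus is a *suspected* source when >= 2 junctions anchored within a
    ``line_window`` of each other each have a remote partner breakend whose
    insert sequence carries a poly-A/poly-T signal.
    """
    cfg = config or Config()

    def in_any(intervals, b: Breakend) -> bool:
        return any(c == b.chromosome and s <= b.position <= e for c, s, e in intervals)

    for j in junctions:
        for b in j.breakends:
            a = annotations.breakends[b.id]
            if in_any(kb.fragile_sites, b):
                a.in_fragile_site = True
            if in_any(kb.line_sources, b):
                a.line_source = "known"

    # suspected sources: anchors whose partner carries a poly-A insert
    anchors: list[tuple[str, int, str, str]] = []   # (chrom, pos, breakend id, junction id)
    for j in junctions:
        if j.end is None:
            continue
        for b, partner in ((j.start, j.end), (j.end, j.start)):
            if has_polya_signal(partner.insert_sequence, cfg.polya_min_length, cfg.polya_purity):
                anchors.append((b.chromosome, b.position, b.id, j.id))
    anchors.sort()
    for i, (chrom, pos, bid, jid) in enumerate(anchors):
        near = {j2 for c2, p2, b2, j2 in anchors
                if c2 == chrom and abs(p2 - pos) <= cfg.line_window}
        if len(near) >= 2:
            a = annotations.breakends[bid]
            if a.line_source == "none":
                a.line_source = "suspected"

    for j in junctions:
        polya = any(has_polya_signal(b.insert_sequence, cfg.polya_min_length, cfg.polya_purity)
                    for b in j.breakends)
        repeat = any((b.repeat_class or "").upper() in ("LINE", "L1", "POLYA")
                     for b in j.breakends)
        in_source = any(annotations.breakends[b.id].line_source != "none" for b in j.breakends)
        if polya or repeat or in_source:
            annotations.line_junctions.add(j.id)


def annotate_phasing(junctions: Sequence[Junction], annotations: AnnotationSet,
                     max_separation: int = 1_000) -> list[PhasePair]:
    """Phase proximate facing breakend pairs as cis / trans / unknown.

    For a facing pair (``+1`` at p_plus, ``-1`` at p_minus) the signed
    distance is ``p_minus - p_plus - 1``; negative distances mean the
    breakends overlap, i.e. the rearrangement duplicated its target site.
    """
    bnds = [b for j in junctions for b in j.breakends]
    for b in bnds:
        annotations.breakends[b.id].phase_groups = list(b.assembly_ids)
    pairs: list[PhasePair] = []
    for i, a in enumerate(bnds):
        for b in bnds[i + 1:]:
            if a.chromosome != b.chromosome or a.orientation == b.orientation:
                continue
            plus, minus = (a, b) if a.orientation == 1 else (b, a)
            distance = minus.position - plus.position - 1
            if abs(distance) > max_separation:
                continue
            if set(a.assembly_ids) & set(b.assembly_ids):
                label = "cis"
            elif a.assembly_ids and b.assembly_ids:
                label = "trans"
            else:
                label = "unknown"
            pairs.append(PhasePair(a.id, b.id, label, distance))
            for x in (a, b):
                ann = annotations.breakends[x.id]
                if ann.nearest_facing_distance is None or abs(distance) < abs(ann.nearest_facing_distance):
                    ann.nearest_facing_distance = distance
    annotations.phase_pairs.extend(pairs)
    return pairs


def annotate_sample(junctions: Sequence[Junction], karyotype: Karyotype,
                    profile: CopyNumberProfile, kb: Optional[KnowledgeBase] = None,
                    config: Optional[Config] = None) -> AnnotationSet:
    """Run the full annotation stage and return the populated set."""
    cfg = config or Config()
    kb = kb or KnowledgeBase()
    ann = annotate_arms_and_geometry(junctions, karyotype)
    detect_foldbacks(junctions, ann, cfg.foldback_max_distance)
    annotate_loh_and_allele_cn(junctions, profile, ann, cfg)
    annotate_fragile_sites_and_line_sources(junctions, kb, ann, cfg)
    annotate_phasing(junctions, ann, cfg.phase_max_separation)
    return ann
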