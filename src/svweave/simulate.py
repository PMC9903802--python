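"""Synthetic rearranged-genome simulator.

Events are scripted onto an explicit derivative-genome representation: each
allele of each chromosome is a *walk* — an ordered list of oriented reference
segments, optionally separated by novel insert text — and extrachromosomal
circles are closed walks with a multiplicity.  The emitted callset is derived
mechanically from the final walks: a junction is any non-reference adjacency
(its JCN the number of derivative copies using it), and the copy-number
profile is per-base walk coverage split by parental allele.  Base-pair
consistency between junctions and copy number therefore holds by
construction, which is exactly the property of the real caller output this
module emulates.

Supported event classes: simple deletion/duplication, reciprocal
inversion/translocation/duplication, shard-insertion (synthetic) deletion
and duplication, chromothripsis (shatter-and-rejoin), breakage-fusion-bridge
ladders, ecDNA circles, LINE insertions (with optional partnered
transduction), and processed-pseudogene insertions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genome_model import (
    Breakend,
    CopyNumberProfile,
    CopyNumberSegment,
    Exon,
    Gene,
    GeneModelCollection,
    Junction,
    Karyotype,
    KnowledgeBase,
    Transcript,
    compute_end_phases,
)

__all__ = [
    "EventSpec",
    "ScriptedEvent",
    "SimulatedSample",
    "DerivativeGenome",
    "simulate_sample",
    "shatter_rejoin",
    "bfb_cycles",
    "emit_callset",
    "toy_gene_model",
    "ALL_EVENT_KINDS",
]

ALL_EVENT_KINDS = (
    "simple_del", "simple_dup", "recip_inv", "recip_trl", "recip_dup",
    "shard_del", "shard_dup", "chromothripsis", "bfb", "ecdna",
    "line_insertion", "pseudogene_insertion",
)

EXPECTED_LABEL = {
    "simple_del": "DEL", "simple_dup": "DUP", "recip_inv": "RECIP_INV",
    "recip_trl": "RECIP_TRL", "recip_dup": "RECIP_DUP", "shard_del": "SYNTH_DEL",
    "shard_dup": "SYNTH_DUP", "chromothripsis": "COMPLEX", "bfb": "COMPLEX",
    "ecdna": "DOUBLE_MINUTE", "line_insertion": "LINE",
    "pseudogene_insertion": "PSEUDOGENE",
}

MAX_RESOLVED_INSERT = 30   # longer novel inserts emit as single-breakend pairs
POLYA = "A" * 60           # literal poly-A standing in for LINE sequence
TSD_LENGTH = 16            # target-site duplication at LINE insertion sites


# ---------------------------------------------------------------------------
# derivative-genome representation
# ---------------------------------------------------------------------------

@dataclass
class WalkSegment:
    chromosome: str
    start: int          # 1-based inclusive
    end: int
    strand: int = 1     # +1 forward, -1 reverse

    def flipped(self) -> "WalkSegment":
        return WalkSegment(self.chromosome, self.start, self.end, -self.strand)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Walk:
    segments: list[WalkSegment]
    inserts: dict[int, str] = field(default_factory=dict)   # text after segment i
    multiplicity: int = 1
    circular: bool = False
    allele: int = 0


class DerivativeGenome:
    def __init__(self, karyotype: Karyotype):
        self.karyotype = karyotype
        self.walks: list[Walk] = []
        for name, chrom in karyotype.chromosomes.items():
            for allele in (0, 1):
                self.walks.append(Walk([WalkSegment(name, 1, chrom.length)], allele=allele))

    def primary_walk(self, chromosome: str, allele: int) -> Walk:
        """The walk holding forward-strand material of the chromosome on the
        given allele (unique while the locus is unrearranged)."""
        for w in self.walks:
            if w.allele != allele:
                continue
            for seg in w.segments:
                if seg.chromosome == chromosome and seg.strand == 1:
                    return w
        raise LookupError(f"no walk holds {chromosome} allele {allele}")

    def edit(self, chromosome: str, allele: int, start: int, end: int,
             replacement: Sequence[WalkSegment | str]) -> None:
        """Replace reference span ``[start, end]`` (``end = start - 1`` for a
        pure insertion) on one allele with the given pieces; strings in the
        replacement become novel insert text between flanking pieces."""
        walk = self._walk_containing(chromosome, allele, start if end >= start else start - 1)
        idx, seg = self._segment_containing(walk, chromosome, start if end >= start else start - 1)
        if end >= start and not (seg.start <= start and end <= seg.end):
            raise ValueError(f"edit span {chromosome}:{start}-{end} not within one pristine segment")

        head = [] if start <= seg.start else [WalkSegment(chromosome, seg.start, start - 1)]
        tail = [] if end >= seg.end else [WalkSegment(chromosome, end + 1, seg.end)]
        pieces = head + list(replacement) + tail

        new_segments: list[WalkSegment] = walk.segments[:idx]
        new_inserts: dict[int, str] = {i: t for i, t in walk.inserts.items() if i < idx}
        pending_insert: Optional[str] = None
        for piece in pieces:
            if isinstance(piece, str):
                pending_insert = (pending_insert or "") + piece
                continue
            if pending_insert is not None:
                new_inserts[len(new_segments) - 1] = pending_insert
                pending_insert = None
            new_segments.append(piece)
        offset = len(new_segments) - (idx + 1)
        for i, t in walk.inserts.items():
            if i >= idx:
                new_inserts[i + offset] = t
        new_segments.extend(walk.segments[idx + 1:])
        walk.segments = new_segments
        walk.inserts = new_inserts

    def split(self, chromosome: str, allele: int, position: int
              ) -> tuple[Walk, list[WalkSegment], list[WalkSegment]]:
        """Split the allele's walk after reference ``position``; returns the
        walk and its head/tail segment lists."""
        walk = self._walk_containing(chromosome, allele, position)
        idx, seg = self._segment_containing(walk, chromosome, position)
        head = walk.segments[:idx]
        tail = walk.segments[idx + 1:]
        if position >= seg.start:
            head = head + [WalkSegment(chromosome, seg.start, position)]
        if position < seg.end:
            tail = [WalkSegment(chromosome, position + 1, seg.end)] + tail
        return walk, head, tail

    def _walk_containing(self, chromosome: str, allele: int, position: int) -> Walk:
        for w in self.walks:
            if w.allele != allele:
                continue
            for seg in w.segments:
                if (seg.chromosome == chromosome and seg.strand == 1
                        and seg.start <= position <= seg.end):
                    return w
        raise LookupError(f"no pristine walk covers {chromosome}:{position} allele {allele}")

    def _segment_containing(self, walk: Walk, chromosome: str, position: int
                            ) -> tuple[int, WalkSegment]:
        for i, seg in enumerate(walk.segments):
            if (seg.chromosome == chromosome and seg.strand == 1
                    and seg.start <= position <= seg.end):
                return i, seg
        raise LookupError(f"segment covering {chromosome}:{position} not found")


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------

def _merge_contiguous(walk: Walk) -> tuple[list[WalkSegment], dict[int, str]]:
    segs: list[WalkSegment] = []
    inserts: dict[int, str] = {}
    for i, seg in enumerate(walk.segments):
        ins_before = walk.inserts.get(i - 1, "") if i > 0 else ""
        if segs and not ins_before:
            prev = segs[-1]
            if (prev.chromosome == seg.chromosome and prev.strand == seg.strand):
                if seg.strand == 1 and seg.start == prev.end + 1:
                    segs[-1] = WalkSegment(seg.chromosome, prev.start, seg.end, 1)
                    continue
                if seg.strand == -1 and seg.end == prev.start - 1:
                    segs[-1] = WalkSegment(seg.chromosome, seg.start, prev.end, -1)
                    continue
        if ins_before:
            inserts[len(segs) - 1] = ins_before
        segs.append(seg)
    return segs, inserts


def _exit_breakend(seg: WalkSegment) -> tuple[str, int, int]:
    """(chrom, pos, orientation) at the traversal exit of a segment."""
    if seg.strand == 1:
        return (seg.chromosome, seg.end, 1)
    return (seg.chromosome, seg.start, -1)


def _entry_breakend(seg: WalkSegment) -> tuple[str, int, int]:
    if seg.strand == 1:
        return (seg.chromosome, seg.start, -1)
    return (seg.chromosome, seg.end, 1)


def emit_callset(genome: DerivativeGenome, noise_sd: float = 0.0,
                 rng: Optional[np.random.Generator] = None
                 ) -> tuple[list[Junction], CopyNumberProfile]:
    """Derive the junction callset and allele-specific copy-number profile
    from the walks.  Junction JCN is the number of derivative copies using
    that adjacency; segment CN is walk coverage per reference base, with the
    minor allele the lesser of the two parental coverages."""
    adjacencies: dict[tuple, float] = {}
    sgls: dict[tuple, float] = {}

    for walk in genome.walks:
        segs, inserts = _merge_contiguous(walk)
        if not segs:
            continue
        pairs = list(zip(range(len(segs) - 1), segs, segs[1:]))
        if walk.circular and len(segs) >= 1:
            pairs.append((len(segs) - 1, segs[-1], segs[0]))
        for i, a, b in pairs:
            insert = inserts.get(i, "")
            ba = _exit_breakend(a)
            bb = _entry_breakend(b)
            if (not insert and a.chromosome == b.chromosome and a.strand == b.strand
                    and ((a.strand == 1 and b.start == a.end + 1)
                         or (a.strand == -1 and b.end == a.start - 1))):
                continue  # reference adjacency (possible around a circular wrap)
            if len(insert) > MAX_RESOLVED_INSERT:
                sgls[(ba, insert)] = sgls.get((ba, insert), 0.0) + walk.multiplicity
                sgls[(bb, insert)] = sgls.get((bb, insert), 0.0) + walk.multiplicity
                continue
            key = (min(ba, bb), max(ba, bb), insert)
            adjacencies[key] = adjacencies.get(key, 0.0) + walk.multiplicity
        if not walk.circular:
            first, last = segs[0], segs[-1]
            bstart = _entry_breakend(first)
            bend = _exit_breakend(last)
            chrom_len = genome.karyotype[first.chromosome].length
            if not (bstart[1] == 1 or bstart[1] == genome.karyotype[bstart[0]].length):
                sgls[(bstart, "")] = sgls.get((bstart, ""), 0.0) + walk.multiplicity
            bend_len = genome.karyotype[bend[0]].length
            if not (bend[1] == 1 or bend[1] == bend_len):
                sgls[(bend, "")] = sgls.get((bend, ""), 0.0) + walk.multiplicity

    junctions: list[Junction] = []
    counter = 0
    for (ba, bb, insert), mult in sorted(adjacencies.items()):
        counter += 1
        jid = f"J{counter:04d}"
        b1 = Breakend(f"{jid}_a", ba[0], ba[1], ba[2], insert_sequence=insert)
        b2 = Breakend(f"{jid}_b", bb[0], bb[1], bb[2])
        junctions.append(Junction(jid, b1, b2, float(mult)))
    for (b, insert), mult in sorted(sgls.items()):
        counter += 1
        jid = f"S{counter:04d}"
        rep = "polyA" if insert and set(insert.upper()) <= {"A"} else None
        b1 = Breakend(f"{jid}_a", b[0], b[1], b[2], insert_sequence=insert, repeat_class=rep)
        junctions.append(Junction(jid, b1, None, float(mult)))

    if noise_sd > 0 and rng is not None:
        for j in junctions:
            j.jcn = max(0.0, j.jcn + float(rng.normal(0.0, noise_sd)))
            j.jcn_low = max(0.0, j.jcn - max(0.5, 2 * noise_sd))
            j.jcn_high = j.jcn + max(0.5, 2 * noise_sd)

    # coverage census
    coverage: dict[str, dict[int, list[tuple[int, int, float]]]] = {}
    for walk in genome.walks:
        for seg in walk.segments:
            coverage.setdefault(seg.chromosome, {}).setdefault(walk.allele, []).append(
                (seg.start, seg.end, walk.multiplicity))
    cn_segments: list[CopyNumberSegment] = []
    for name, chrom in genome.karyotype.chromosomes.items():
        by_allele = coverage.get(name, {})
        points = {1, chrom.length + 1}
        for ivs in by_allele.values():
            for s, e, _ in ivs:
                points.update((s, e + 1))
        pts = sorted(p for p in points if 1 <= p <= chrom.length + 1)
        raw: list[tuple[int, int, float, float]] = []
        for p, q in zip(pts, pts[1:]):
            covs = []
            for allele in (0, 1):
                covs.append(sum(m for s, e, m in by_allele.get(allele, [])
                                if s <= p and e >= q - 1))
            total = covs[0] + covs[1]
            minor = min(covs)
            if raw and raw[-1][2] == total and raw[-1][3] == minor:
                raw[-1] = (raw[-1][0], q, total, minor)
            else:
                raw.append((p, q, total, minor))
        cn_segments.extend(CopyNumberSegment(name, s, e, t, m) for s, e, t, m in raw)
    return junctions, CopyNumberProfile(cn_segments)


# ---------------------------------------------------------------------------
# toy gene model
# ---------------------------------------------------------------------------

def _make_gene(name: str, chromosome: str, strand: str, tx_start: int,
               n_exons: int, exon_len: int, intron_len: int) -> Gene:
    coords = []
    pos = tx_start
    for _ in range(n_exons):
        coords.append((pos, pos + exon_len - 1))
        pos += exon_len + intron_len
    cs, ce = coords[0][0] + 30, coords[-1][1] - 30
    tx_order = coords if strand == "+" else coords[::-1]
    phases = compute_end_phases(tx_order, strand, cs, ce)
    exons = [Exon(s, e, p) for (s, e), p in zip(tx_order, phases)]
    return Gene(name, chromosome, strand, [Transcript(f"{name}-201", exons, cs, ce)])


def toy_gene_model() -> GeneModelCollection:
    """Fixed small gene model used by simulated samples: a 16-exon
    pseudogene-donor transcript plus fusion/disruption target genes."""
    return GeneModelCollection([
        _make_gene("PGD1", "chr4", "+", 5_000_000, 16, 150, 2_500),
        _make_gene("FUS5", "chr1", "+", 8_000_000, 10, 200, 5_000),
        _make_gene("FUS3", "chr2", "+", 8_000_000, 12, 200, 5_000),
        _make_gene("TSG1", "chr3", "+", 30_000_000, 8, 300, 4_000),
        _make_gene("ONC1", "chr3", "+", 5_000_000, 5, 300, 4_000),
    ])


# ---------------------------------------------------------------------------
# event scripting
# ---------------------------------------------------------------------------

@dataclass
class EventSpec:
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ALL_EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "chromothripsis" and self.params.get("n_breaks", 30) < 3:
            raise ValueError("chromothripsis requires n_breaks >= 3")


@dataclass
class ScriptedEvent:
    kind: str
    expected_label: str
    footprints: list[tuple[str, int, int]]
    params: dict = field(default_factory=dict)
    junction_ids: list[str] = field(default_factory=list)


@dataclass
class SimulatedSample:
    karyotype: Karyotype
    junctions: list[Junction]
    profile: CopyNumberProfile
    truth: list[ScriptedEvent]
    knowledgebase: KnowledgeBase
    gene_model: GeneModelCollection
    genome: DerivativeGenome


class _Placer:
    """Reserves disjoint reference intervals for events, with spacing so
    independently scripted events cannot merge through proximity or run
    bounding."""

    MARGIN = 2_000_000      # keep away from telomeres and centromere
    SPACING = 300_000       # buffer between reserved intervals

    def __init__(self, karyotype: Karyotype, rng: np.random.Generator,
                 reserved: Optional[list[tuple[str, int, int]]] = None):
        self.karyotype = karyotype
        self.rng = rng
        self.reserved: list[tuple[str, int, int]] = list(reserved or [])

    def reserve(self, length: int, chromosome: Optional[str] = None,
                arm: Optional[str] = None, tries: int = 200) -> tuple[str, int, int]:
        names = sorted(self.karyotype.chromosomes)
        for _ in range(tries):
            chrom = chromosome or names[int(self.rng.integers(len(names)))]
            c = self.karyotype[chrom]
            a = arm or ("P" if self.rng.random() < 0.5 else "Q")
            if a == "P":
                lo, hi = self.MARGIN, c.centromere_start - self.MARGIN
            else:
                lo, hi = c.centromere_end + self.MARGIN, c.length - self.MARGIN
            if hi - lo < length + 2 * self.SPACING:
                continue
            start = int(self.rng.integers(lo, hi - length))
            end = start + length
            clash = any(ch == chrom and not (end + self.SPACING < s or start - self.SPACING > e)
                        for ch, s, e in self.reserved)
            if not clash:
                self.reserved.append((chrom, start, end))
                return chrom, start, end
        raise RuntimeError(f"could not place an interval of length {length}")


def _ilen(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _apply_event(genome: DerivativeGenome, spec: EventSpec, placer: _Placer,
                 rng: np.random.Generator, kb: KnowledgeBase,
                 gene_model: GeneModelCollection) -> ScriptedEvent:
    kind, p = spec.kind, dict(spec.params)
    ev = ScriptedEvent(kind, EXPECTED_LABEL[kind], [], p)

    if kind == "simple_del":
        length = p.get("length") or _ilen(rng, 10_000, 100_000)
        chrom, a, b = placer.reserve(length)
        genome.edit(chrom, 0, a, b, [])
        ev.footprints = [(chrom, a - 1, b + 1)]

    elif kind == "simple_dup":
        length = p.get("length") or _ilen(rng, 10_000, 100_000)
        chrom, a, b = placer.reserve(length)
        genome.edit(chrom, 0, a, b,
                    [WalkSegment(chrom, a, b), WalkSegment(chrom, a, b)])
        ev.footprints = [(chrom, a - 1, b + 1)]

    elif kind == "recip_inv":
        length = p.get("length") or _ilen(rng, 50_000, 2_000_000)
        chrom, a, b = placer.reserve(length)
        genome.edit(chrom, 0, a, b, [WalkSegment(chrom, a, b, -1)])
        ev.footprints = [(chrom, a - 1, b + 1)]

    elif kind == "recip_trl":
        c1, p1, _ = placer.reserve(1000)
        c2 = None
        names = [n for n in sorted(genome.karyotype.chromosomes) if n != c1]
        c2 = names[int(rng.integers(len(names)))]
        c2, p2, _ = placer.reserve(1000, chromosome=c2)
        w1, head1, tail1 = genome.split(c1, 0, p1)
        w2, head2, tail2 = genome.split(c2, 0, p2)
        w1.segments, w1.inserts = head1 + tail2, {}
        w2.segments, w2.inserts = head2 + tail1, {}
        ev.footprints = [(c1, p1 - 1, p1 + 2), (c2, p2 - 1, p2 + 2)]

    elif kind == "recip_dup":
        ov1 = p.get("overlap") or _ilen(rng, 20_000, 500_000)
        ov2 = _ilen(rng, 20_000, 500_000)
        c1, a1, a2 = placer.reserve(ov1)
        names = [n for n in sorted(genome.karyotype.chromosomes) if n != c1]
        c2 = names[int(rng.integers(len(names)))]
        c2, b1, b2 = placer.reserve(ov2, chromosome=c2)
        w1, head1_a2, tail1_a2 = genome.split(c1, 0, a2)
        w2, head2_b2, tail2_b2 = genome.split(c2, 0, b2)
        # derivative 1: chr1 up to a2 then chr2 from b1 on
        # derivative 2: chr2 up to b2 then chr1 from a1 on
        tail2_from_b1 = [WalkSegment(c2, b1, b2)] + tail2_b2
        tail1_from_a1 = [WalkSegment(c1, a1, a2)] + tail1_a2
        w1.segments, w1.inserts = head1_a2 + tail2_from_b1, {}
        w2.segments, w2.inserts = head2_b2 + tail1_from_a1, {}
        ev.footprints = [(c1, a1 - 1, a2 + 1), (c2, b1 - 1, b2 + 1)]

    elif kind in ("shard_del", "shard_dup"):
        length = p.get("length") or _ilen(rng, 10_000, 100_000)
        shard_len = p.get("shard_length") or int(rng.integers(100, 900))
        chrom, a, b = placer.reserve(length)
        names = [n for n in sorted(genome.karyotype.chromosomes) if n != chrom]
        dchrom = names[int(rng.integers(len(names)))]
        dchrom, d1, d2 = placer.reserve(shard_len, chromosome=dchrom)
        donor = WalkSegment(dchrom, d1, d2)
        if kind == "shard_del":
            genome.edit(chrom, 0, a, b, [donor])
        else:
            genome.edit(chrom, 0, a, b,
                        [WalkSegment(chrom, a, b), donor, WalkSegment(chrom, a, b)])
        ev.footprints = [(chrom, a - 1, b + 1), (dchrom, d1 - 1, d2 + 1)]

    elif kind == "chromothripsis":
        n = p.get("n_breaks", 30)
        retention = p.get("retention", 0.95)
        length = p.get("length") or 10_000_000
        chrom, a, b = placer.reserve(length)
        replacement = _shatter_plan(rng, chrom, a, b, n, retention)
        genome.edit(chrom, 0, a, b, replacement)
        ev.footprints = [(chrom, a - 1, b + 1)]

    elif kind == "bfb":
        # rebuilds the chromosome walk, so it needs a pristine chromosome
        # with a reservation-free Q arm; the amplified arm is then blocked
        n = p.get("n_cycles", 4)
        candidates = []
        for name in sorted(genome.karyotype.chromosomes):
            c = genome.karyotype[name]
            walk = genome.primary_walk(name, 0)
            pristine = (len(walk.segments) == 1 and walk.segments[0].start == 1
                        and walk.segments[0].end == c.length)
            q_clear = not any(ch == name and e > c.centromere_end
                              for ch, s, e in placer.reserved)
            if pristine and q_clear:
                candidates.append(name)
        if not candidates:
            raise RuntimeError("no pristine chromosome available for a BFB event")
        chrom = candidates[int(rng.integers(len(candidates)))]
        c = genome.karyotype[chrom]
        lo, hi = c.centromere_end + 2_000_000, c.length - 2_000_000
        folds = sorted(set(rng.integers(lo, hi, size=n + 1).tolist()), reverse=True)
        while len(folds) < n + 1:
            folds.append(folds[-1] - int(rng.integers(10_000, 50_000)))
        _apply_bfb(genome, chrom, 0, folds[: n + 1])
        placer.reserved.append((chrom, folds[-1] - placer.SPACING, c.length))
        ev.footprints = [(chrom, folds[-1] - 1, c.length)]

    elif kind == "ecdna":
        n_seg = p.get("n_segments", 3)
        copies = p.get("copies", 23)
        seglen = p.get("segment_length") or 120_000
        segments = []
        for attempt in range(10):
            chrom = p.get("chromosome")
            marker = len(placer.reserved)
            try:
                for _ in range(n_seg):
                    c, s, e = placer.reserve(seglen, chromosome=chrom, arm="Q")
                    chrom = c   # all loop segments share one arm
                    segments.append(WalkSegment(c, s, e))
                break
            except RuntimeError:
                del placer.reserved[marker:]
                segments.clear()
        if not segments:
            raise RuntimeError("could not place ecDNA loop segments")
        segments.sort(key=lambda s: s.start)
        genome.walks.append(Walk(segments, multiplicity=copies, circular=True, allele=0))
        ev.footprints = [(s.chromosome, s.start - 1, s.end + 1) for s in segments]

    elif kind == "line_insertion":
        transduced = p.get("transduction", False)
        chrom, t, _ = placer.reserve(1000)
        tsd = WalkSegment(chrom, t + 1, t + TSD_LENGTH)
        if transduced:
            schrom, s1, res_end = placer.reserve(12_000)
            s2 = s1 + 6_000
            kb.line_sources.append((schrom, s1, s2))
            frag_len = int(rng.integers(1_000, 4_000))
            frag = WalkSegment(schrom, s2 + 100, s2 + 100 + frag_len)
            genome.edit(chrom, 0, t + 1, t + TSD_LENGTH,
                        [tsd, frag, "A" * 20, dataclasses.replace(tsd)])
            ev.footprints = [(chrom, t - 1, t + TSD_LENGTH + 2),
                             (schrom, s1 - 1, s2 + 100 + frag_len + 1)]
        else:
            genome.edit(chrom, 0, t + 1, t + TSD_LENGTH,
                        [tsd, POLYA, dataclasses.replace(tsd)])
            ev.footprints = [(chrom, t - 1, t + TSD_LENGTH + 2)]

    elif kind == "pseudogene_insertion":
        gene_name = p.get("gene", "PGD1")
        gene = gene_model[gene_name]
        tx = gene.canonical()
        exons = sorted(tx.exons, key=lambda e: e.start)
        host_names = [n for n in sorted(genome.karyotype.chromosomes) if n != gene.chromosome]
        hchrom = host_names[int(rng.integers(len(host_names)))]
        hchrom, t, _ = placer.reserve(1000, chromosome=hchrom)
        pieces = [WalkSegment(gene.chromosome, e.start, e.end) for e in exons]
        genome.edit(hchrom, 0, t + 1, t, pieces)
        span = (gene.chromosome, exons[0].start - 1, exons[-1].end + 1)
        ev.footprints = [(hchrom, t - 1, t + 2), span]

    else:  # pragma: no cover
        raise AssertionError(kind)
    return ev


def _shatter_plan(rng: np.random.Generator, chrom: str, a: int, b: int,
                  n_breaks: int, retention: float,
                  permutation: Optional[Sequence[int]] = None,
                  flips: Optional[Sequence[bool]] = None,
                  keep: Optional[Sequence[bool]] = None) -> list[WalkSegment]:
    cuts: set[int] = set()
    while len(cuts) < n_breaks:
        cuts.update(rng.integers(a + 1, b - 1, size=n_breaks - len(cuts)).tolist())
    cuts = sorted(cuts)
    bounds = [a] + [c + 1 for c in cuts] + [b + 1]
    fragments = [WalkSegment(chrom, s, e - 1) for s, e in zip(bounds, bounds[1:])]
    if keep is None:
        keep = rng.random(len(fragments)) < retention
    retained = [f for f, k in zip(fragments, keep) if k]
    if permutation is None:
        permutation = rng.permutation(len(retained)).tolist()
    retained = [retained[i] for i in permutation]
    if flips is None:
        flips = rng.random(len(retained)) < 0.5
    return [f.flipped() if fl else f for f, fl in zip(retained, flips)]


def _apply_bfb(genome: DerivativeGenome, chromosome: str, allele: int,
               folds: Sequence[int]) -> None:
    """Apply breakage-fusion-bridge cycles at descending Q-arm fold positions
    ``folds[0] > folds[1] > ...``; the final break remains an unhealed single
    breakend.  Each cycle appends the reverse of the current walk, clipped at
    the next fold, doubling everything distal of it."""
    p1, rest = folds[0], folds[1:]
    walk = genome.primary_walk(chromosome, allele)
    segs: list[WalkSegment] = [WalkSegment(chromosome, 1, p1)]
    for r in rest:
        mirrored = [s.flipped() for s in reversed(segs)]
        last = mirrored[-1]
        # the appended sister copy breaks when the bridge snaps at ref r
        if last.strand == -1:
            mirrored[-1] = WalkSegment(chromosome, r, last.end, -1)
        else:
            mirrored[-1] = WalkSegment(chromosome, last.start, r, 1)
        segs = segs + mirrored
    walk.segments = segs
    walk.inserts = {}


def simulate_sample(specs: Sequence[EventSpec], karyotype: Optional[Karyotype] = None,
                    seed: int = 0, noise_sd: float = 0.0,
                    gene_model: Optional[GeneModelCollection] = None) -> SimulatedSample:
    """Script the given events onto a fresh diploid genome and emit the
    callset, ground truth, and per-sample knowledgebase.

    Events are placed at disjoint loci (retrying placement up to a bound);
    every emitted callset passes base-pair consistency at tolerance 0.01.
    """
    karyotype = karyotype or Karyotype.toy()
    gene_model = gene_model or toy_gene_model()
    rng = np.random.default_rng(seed)
    genome = DerivativeGenome(karyotype)
    kb = KnowledgeBase()

    reserved = []
    for gene in gene_model:
        lo, hi = gene.span()
        reserved.append((gene.chromosome, lo - 10_000, hi + 10_000))
    placer = _Placer(karyotype, rng, reserved)

    # BFB events rebuild whole-chromosome walks, so they are applied first;
    # other events then splice into the surviving arms
    ordered = sorted(specs, key=lambda sp: sp.kind != "bfb")
    truth = []
    for spec in ordered:
        truth.append(_apply_event(genome, spec, placer, rng, kb, gene_model))

    junctions, profile = emit_callset(genome, noise_sd, rng)

    owned: set[str] = set()
    for ev in truth:
        pads = [(c, s - 10, e + 10) for c, s, e in ev.footprints]
        for j in junctions:
            if j.id in owned:
                continue
            if any(b.chromosome == c and s <= b.position <= e
                   for b in j.breakends for c, s, e in pads):
                ev.junction_ids.append(j.id)
                owned.add(j.id)

    return SimulatedSample(karyotype, junctions, profile, truth, kb, gene_model, genome)


# ---------------------------------------------------------------------------
# standalone operations
# ---------------------------------------------------------------------------

def shatter_rejoin(karyotype: Karyotype, chromosome: str, start: int, end: int,
                   n_breaks: int, retention: float = 1.0, seed: int = 0,
                   permutation: Optional[Sequence[int]] = None,
                   flips: Optional[Sequence[bool]] = None,
                   keep: Optional[Sequence[bool]] = None,
                   ) -> tuple[list[Junction], CopyNumberProfile]:
    """Shatter one interval of one allele into ``n_breaks + 1`` fragments,
    drop each with probability ``1 - retention``, permute and randomly flip
    the survivors, and rejoin.  Junctions and CN are derived from the
    resulting walk; with identity permutation, full retention and no flips
    the genome is unchanged and no junctions are emitted."""
    if n_breaks < 3:
        raise ValueError("shatter requires n_breaks >= 3")
    rng = np.random.default_rng(seed)
    genome = DerivativeGenome(karyotype)
    replacement = _shatter_plan(rng, chromosome, start, end, n_breaks, retention,
                                permutation, flips, keep)
    genome.edit(chromosome, 0, start, end, replacement)
    return emit_callset(genome)


def simulate_enrichment_cohort(n_genes: int = 100, mean_lambda: float = 2.0,
                               enriched_gene: str = "G000", fold: float = 10.0,
                               seed: int = 0) -> tuple[dict[str, int], dict[str, float]]:
    """Cohort-scale homozygous-disruption counts for the enrichment test.

    Gene lengths are log-normal around 100 kb; baseline counts are Poisson
    with a per-gene expectation proportional to length (cohort-level mean
    ``mean_lambda``); one gene's rate is multiplied by ``fold``.  Returns
    (counts, lengths).
    """
    rng = np.random.default_rng(seed)
    names = [f"G{i:03d}" for i in range(n_genes)]
    lengths = {g: float(np.exp(rng.normal(np.log(100_000), 0.5))) for g in names}
    mean_len = float(np.mean(list(lengths.values())))
    rate = mean_lambda / mean_len
    counts = {}
    for g in names:
        lam = rate * lengths[g] * (fold if g == enriched_gene else 1.0)
        counts[g] = int(rng.poisson(lam))
    return counts, lengths


def bfb_cycles(karyotype: Karyotype, chromosome: str, n_cycles: int, seed: int = 0
               ) -> tuple[list[Junction], CopyNumberProfile]:
    """Run ``n_cycles`` breakage-fusion-bridge cycles on one allele of the Q
    arm; each cycle emits one foldback inversion and doubles coverage distal
    of the fold, giving a stepped copy-number ladder."""
    if n_cycles < 1:
        raise ValueError("bfb requires n_cycles >= 1")
    rng = np.random.default_rng(seed)
    c = karyotype[chromosome]
    lo = c.centromere_end + 2_000_000
    hi = c.length - 2_000_000
    folds = sorted(set(rng.integers(lo, hi, size=n_cycles + 1).tolist()), reverse=True)
    while len(folds) < n_cycles + 1:
        folds.append(folds[-1] - int(rng.integers(10_000, 50_000)))
    genome = DerivativeGenome(karyotype)
    _apply_bfb(genome, chromosome, 0, folds[: n_cycles + 1])
    return emit_callset(genome)
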