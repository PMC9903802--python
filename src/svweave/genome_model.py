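"""Core domain model for somatic structural-variant interpretation.

Positions are 1-based inclusive for breakends (matching VCF); copy-number
segments are half-open ``[start, end)``.  Breakend orientation is encoded as
``+1`` when the retained genomic material extends toward *lower* coordinates
from the break (the VCF ``t[p[`` / ``t]p]`` side) and ``-1`` when it extends
toward higher coordinates.  Under this convention a deletion junction is
``(+1, -1)`` with the ``+1`` breakend at the lower position, and a tandem
duplication is ``(-1, +1)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from intervaltree import IntervalTree

__all__ = [
    "Chromosome",
    "Karyotype",
    "Breakend",
    "Junction",
    "CopyNumberSegment",
    "CopyNumberProfile",
    "Exon",
    "Transcript",
    "Gene",
    "GeneModelCollection",
    "KnowledgeBase",
    "IgRegion",
    "ConsistencyViolation",
    "ConsistencyReport",
    "derive_sv_type",
    "read_junctions",
    "write_junctions",
    "read_copy_segments",
    "write_copy_segments",
    "read_gene_model",
    "validate_bp_consistency",
]

LOH_THRESHOLD = 0.5          # minor-allele CN below this is LOH
HOMDEL_THRESHOLD = 0.5       # total CN below this is homozygous deletion
DEFAULT_JCN_UNCERTAINTY = 0.5


# ---------------------------------------------------------------------------
# karyotype
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere_start: int
    centromere_end: int

    def __post_init__(self) -> None:
        if not (0 < self.centromere_start < self.centromere_end < self.length):
            raise ValueError(
                f"invalid centromere interval for {self.name}: "
                f"{self.centromere_start}-{self.centromere_end} (length {self.length})"
            )


class Karyotype:
    """Chromosome lengths and centromere intervals; assigns arm membership."""

    def __init__(self, chromosomes: Iterable[Chromosome]):
        self.chromosomes: dict[str, Chromosome] = {}
        for c in chromosomes:
            if c.name in self.chromosomes:
                raise ValueError(f"duplicate chromosome {c.name}")
            self.chromosomes[c.name] = c

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __getitem__(self, name: str) -> Chromosome:
        return self.chromosomes[name]

    def arm_of(self, chromosome: str, position: int) -> str:
        """Arm (``"P"`` or ``"Q"``) of a position; centromeric positions are
        assigned the nearer arm."""
        c = self.chromosomes[chromosome]
        if position < c.centromere_start:
            return "P"
        if position > c.centromere_end:
            return "Q"
        mid = (c.centromere_start + c.centromere_end) / 2
        return "P" if position <= mid else "Q"

    def in_centromere(self, chromosome: str, position: int) -> bool:
        c = self.chromosomes[chromosome]
        return c.centromere_start <= position <= c.centromere_end

    @classmethod
    def toy(cls, n_chromosomes: int = 4, length: int = 50_000_000,
            centromere: int = 20_000_000, centromere_width: int = 100_000) -> "Karyotype":
        """Small synthetic karyotype used by the simulator and tests."""
        return cls(
            Chromosome(f"chr{i + 1}", length, centromere, centromere + centromere_width)
            for i in range(n_chromosomes)
        )


# ---------------------------------------------------------------------------
# breakends and junctions
# ---------------------------------------------------------------------------

@dataclass
class Breakend:
    id: str
    chromosome: str
    position: int
    orientation: int
    insert_sequence: str = ""
    homology_length: int = 0
    assembly_ids: list[str] = field(default_factory=list)
    repeat_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"breakend {self.id}: position must be >= 1")
        if self.orientation not in (1, -1):
            raise ValueError(f"breakend {self.id}: orientation must be +1 or -1")


def derive_sv_type(start: Breakend, end: Optional[Breakend]) -> str:
    """Classify a junction from its breakend chromosomes and orientations.

    Pure function: DEL = (+1 lower, -1 higher), DUP = (-1 lower, +1 higher),
    INV = equal orientations, TRL = different chromosomes, SGL = unmated.
    """
    if end is None:
        return "SGL"
    if start.chromosome != end.chromosome:
        return "TRL"
    if start.orientation == end.orientation:
        return "INV"
    lo, hi = sorted((start, end), key=lambda b: (b.position, -b.orientation))
    return "DEL" if lo.orientation == 1 else "DUP"


@dataclass
class Junction:
    id: str
    start: Breakend
    end: Optional[Breakend]
    jcn: float = 1.0
    jcn_low: Optional[float] = None
    jcn_high: Optional[float] = None

    def __post_init__(self) -> None:
        if self.jcn < 0:
            raise ValueError(f"junction {self.id}: jcn must be >= 0")
        if self.jcn_low is None:
            self.jcn_low = max(0.0, self.jcn - DEFAULT_JCN_UNCERTAINTY)
        if self.jcn_high is None:
            self.jcn_high = self.jcn + DEFAULT_JCN_UNCERTAINTY
        if not (self.jcn_low <= self.jcn <= self.jcn_high):
            raise ValueError(f"junction {self.id}: jcn bounds must bracket jcn")

    @property
    def sv_type(self) -> str:
        return derive_sv_type(self.start, self.end)

    @property
    def breakends(self) -> tuple[Breakend, ...]:
        return (self.start,) if self.end is None else (self.start, self.end)

    @property
    def length(self) -> Optional[int]:
        """|p_end - p_start| for intrachromosomal junctions, else None."""
        if self.end is None or self.start.chromosome != self.end.chromosome:
            return None
        return abs(self.end.position - self.start.position)

    @property
    def insert_sequence(self) -> str:
        return self.start.insert_sequence or (self.end.insert_sequence if self.end else "")


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CopyNumberSegment:
    chromosome: str
    start: int          # half-open [start, end)
    end: int
    cn_total: float
    cn_minor: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"segment {self.chromosome}:{self.start}-{self.end}: empty interval")
        if self.cn_total < 0 or self.cn_minor < 0:
            raise ValueError("copy numbers must be >= 0")

    @property
    def cn_major(self) -> float:
        return self.cn_total - self.cn_minor


class CopyNumberProfile:
    """Per-chromosome ordered, gap-free, non-overlapping CN segments."""

    MINOR_TOLERANCE = 0.11

    def __init__(self, segments: Iterable[CopyNumberSegment]):
        self.by_chromosome: dict[str, list[CopyNumberSegment]] = {}
        for seg in segments:
            self.by_chromosome.setdefault(seg.chromosome, []).append(seg)
        for chrom, segs in self.by_chromosome.items():
            segs.sort(key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start != a.end:
                    kind = "gap" if b.start > a.end else "overlap"
                    raise ValueError(
                        f"{kind} between segments on {chrom}: "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )
            for s in segs:
                if s.cn_minor > s.cn_total / 2 + self.MINOR_TOLERANCE:
                    raise ValueError(
                        f"segment {chrom}:{s.start}-{s.end}: minor CN {s.cn_minor} "
                        f"exceeds half of total {s.cn_total}"
                    )

    def segments(self, chromosome: str) -> list[CopyNumberSegment]:
        return self.by_chromosome.get(chromosome, [])

    def all_segments(self) -> Iterator[CopyNumberSegment]:
        for chrom in sorted(self.by_chromosome):
            yield from self.by_chromosome[chrom]

    def segment_at(self, chromosome: str, position: int) -> Optional[CopyNumberSegment]:
        for s in self.by_chromosome.get(chromosome, []):
            if s.start <= position < s.end:
                return s
        return None

    def cn_at(self, chromosome: str, position: int) -> float:
        s = self.segment_at(chromosome, position)
        return s.cn_total if s is not None else 0.0

    def minor_at(self, chromosome: str, position: int) -> float:
        s = self.segment_at(chromosome, position)
        return s.cn_minor if s is not None else 0.0

    def min_cn(self, chromosome: str, start: int, end: int) -> float:
        """Minimum total CN over the 1-based inclusive interval [start, end]."""
        vals = [s.cn_total for s in self.by_chromosome.get(chromosome, [])
                if s.start <= end and s.end > start]
        return min(vals) if vals else 0.0

    def boundaries(self, chromosome: str) -> list[int]:
        segs = self.by_chromosome.get(chromosome, [])
        return [s.start for s in segs[1:]]


# ---------------------------------------------------------------------------
# gene model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Exon:
    start: int            # genomic, 1-based inclusive
    end: int
    end_phase: int = -1   # phase after this exon in transcript orientation


@dataclass
class Transcript:
    id: str
    exons: list[Exon]                 # ordered 5'->3' in transcript orientation
    coding_start: Optional[int] = None  # genomic coordinates, start <= end
    coding_end: Optional[int] = None

    @property
    def is_coding(self) -> bool:
        return self.coding_start is not None

    def genomic_span(self) -> tuple[int, int]:
        lo = min(e.start for e in self.exons)
        hi = max(e.end for e in self.exons)
        return lo, hi


@dataclass
class Gene:
    name: str
    chromosome: str
    strand: str                       # '+' or '-'
    transcripts: list[Transcript]

    def canonical(self) -> Transcript:
        return self.transcripts[0]

    def span(self) -> tuple[int, int]:
        lo = min(t.genomic_span()[0] for t in self.transcripts)
        hi = max(t.genomic_span()[1] for t in self.transcripts)
        return lo, hi


class GeneModelCollection:
    """Genes indexed by name and by genomic interval."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: dict[str, Gene] = {g.name: g for g in genes}
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes.values():
            lo, hi = g.span()
            self._trees.setdefault(g.chromosome, IntervalTree()).addi(lo, hi + 1, g)

    def __contains__(self, name: str) -> bool:
        return name in self.genes

    def __getitem__(self, name: str) -> Gene:
        return self.genes[name]

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes.values())

    def overlapping(self, chromosome: str, start: int, end: Optional[int] = None) -> list[Gene]:
        tree = self._trees.get(chromosome)
        if tree is None:
            return []
        end = start if end is None else end
        return sorted((iv.data for iv in tree.overlap(start, end + 1)), key=lambda g: g.name)


def compute_end_phases(exons_tx_order: list[tuple[int, int]], strand: str,
                       coding_start: Optional[int], coding_end: Optional[int]) -> list[int]:
    """End phase per exon = cumulative coding length mod 3 at the exon's 3'
    boundary; -1 where the transcript is non-coding at that boundary."""
    if coding_start is None or coding_end is None:
        return [-1] * len(exons_tx_order)
    phases = []
    cum = 0
    for (s, e) in exons_tx_order:
        ov = min(e, coding_end) - max(s, coding_start) + 1
        if ov > 0:
            cum += ov
        # 3' boundary of this exon in transcript orientation
        boundary = e if strand == "+" else s
        past_cds_end = (boundary > coding_end) if strand == "+" else (boundary < coding_start)
        if cum == 0 or past_cds_end:
            phases.append(-1)
        else:
            phases.append(cum % 3)
    return phases


# ---------------------------------------------------------------------------
# knowledgebase
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IgRegion:
    name: str               # IGH / IGK / IGL
    chromosome: str
    start: int
    end: int
    orientation: int        # required breakend orientation inside the region


@dataclass
class KnowledgeBase:
    known_fusion_pairs: list[tuple[str, str]] = field(default_factory=list)
    promiscuous_5p: list[str] = field(default_factory=list)
    promiscuous_3p: list[str] = field(default_factory=list)
    fragile_sites: list[tuple[str, int, int]] = field(default_factory=list)
    line_sources: list[tuple[str, int, int]] = field(default_factory=list)
    ig_regions: list[IgRegion] = field(default_factory=list)
    driver_panel: list[str] = field(default_factory=list)
    pathogenic_exon_rearrangements: list[tuple[str, int, int, str]] = field(default_factory=list)

    def validate_against(self, gene_model: GeneModelCollection) -> list[str]:
        """Return warnings for gene names that do not resolve."""
        warnings = []
        names = set()
        for a, b in self.known_fusion_pairs:
            names.update((a, b))
        names.update(self.promiscuous_5p, self.promiscuous_3p, self.driver_panel)
        names.update(g for g, *_ in self.pathogenic_exon_rearrangements)
        for n in sorted(names):
            if n not in gene_model:
                warnings.append(f"knowledgebase gene {n!r} not in gene model")
        return warnings

    @classmethod
    def load(cls, directory: str | Path) -> "KnowledgeBase":
        """Load from a directory of TSV tables; missing tables are empty."""
        d = Path(directory)
        kb = cls()

        def rows(name: str) -> list[list[str]]:
            p = d / name
            if not p.exists():
                return []
            out = []
            with open(p) as fh:
                header = fh.readline()
                for line in fh:
                    line = line.rstrip("\n")
                    if line:
                        out.append(line.split("\t"))
            return out

        kb.known_fusion_pairs = [(r[0], r[1]) for r in rows("known_fusion_pairs.tsv")]
        for r in rows("promiscuous_partners.tsv"):
            (kb.promiscuous_5p if r[1].upper() == "5P" else kb.promiscuous_3p).append(r[0])
        kb.fragile_sites = [(r[0], int(r[1]), int(r[2])) for r in rows("fragile_sites.tsv")]
        kb.line_sources = [(r[0], int(r[1]), int(r[2])) for r in rows("line_sources.tsv")]
        kb.ig_regions = [IgRegion(r[0], r[1], int(r[2]), int(r[3]), int(r[4]))
                         for r in rows("ig_regions.tsv")]
        kb.driver_panel = [r[0] for r in rows("driver_panel.tsv")]
        kb.pathogenic_exon_rearrangements = [
            (r[0], int(r[1]), int(r[2]), r[3]) for r in rows("pathogenic_exon_rearrangements.tsv")
        ]
        for name, start, end in kb.fragile_sites + kb.line_sources:
            if end < start:
                raise ValueError(f"invalid knowledgebase interval {name}:{start}-{end}")
        return kb


# ---------------------------------------------------------------------------
# junction I/O
# ---------------------------------------------------------------------------

_BND_RE = re.compile(r"^(?P<lead>[A-Za-z.*]*)(?P<open>[\[\]])(?P<chrom>[^:]+):(?P<pos>\d+)(?P<close>[\[\]])(?P<trail>[A-Za-z.*]*)$")

_TSV_HEADER = [
    "id", "chrom1", "pos1", "orient1", "insert1", "asm1", "repeat1",
    "chrom2", "pos2", "orient2", "insert2", "asm2", "repeat2",
    "jcn", "jcn_low", "jcn_high", "homlen",
]


class JunctionParseError(ValueError):
    pass


def _parse_bnd_alt(record_id: str, alt: str) -> tuple[int, str, int, int, str]:
    """Return (local orientation, mate chrom, mate pos, mate orientation, insert)."""
    m = _BND_RE.match(alt)
    if m is None:
        raise JunctionParseError(f"malformed BND ALT {alt!r} in record {record_id}")
    if m.group("open") != m.group("close"):
        raise JunctionParseError(f"mismatched brackets in ALT {alt!r} of record {record_id}")
    lead, trail = m.group("lead"), m.group("trail")
    local_orient = 1 if lead else -1
    mate_orient = -1 if m.group("open") == "[" else 1
    insert = (lead[1:] if local_orient == 1 else trail[:-1]) if (lead or trail) else ""
    return local_orient, m.group("chrom"), int(m.group("pos")), mate_orient, insert


def _read_junctions_vcf(path: str | Path) -> list[Junction]:
    import pysam

    records: dict[str, dict] = {}
    order: list[str] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alt = rec.alts[0] if rec.alts else ""
            info = dict(rec.info)
            records[rec.id] = {
                "chrom": rec.chrom, "pos": rec.pos, "alt": alt, "info": info,
            }
            order.append(rec.id)

    junctions: list[Junction] = []
    seen: set[str] = set()
    for rid in order:
        if rid in seen:
            continue
        rec = records[rid]
        info = rec["info"]
        jcn = float(info.get("JCN", 1.0))
        jcn_low = float(info["JCNLO"]) if "JCNLO" in info else None
        jcn_high = float(info["JCNHI"]) if "JCNHI" in info else None
        homlen = int(info.get("HOMLEN", 0))
        asm = list(info.get("BEID", ())) if "BEID" in info else []
        repclass = info.get("REPCLASS")

        alt = rec["alt"]
        if "[" not in alt and "]" not in alt:
            # single breakend: 's.' retains lower coordinates, '.s' higher
            if alt.endswith("."):
                orient, insert = 1, alt[1:-1]
            elif alt.startswith("."):
                orient, insert = -1, alt[1:-1]
            else:
                raise JunctionParseError(f"malformed single-breakend ALT {alt!r} in record {rid}")
            be = Breakend(rid, rec["chrom"], rec["pos"], orient, insert, homlen, asm, repclass)
            junctions.append(Junction(rid.rsplit("_", 1)[0] if rid.endswith("_b") else rid,
                                      be, None, jcn, jcn_low, jcn_high))
            seen.add(rid)
            continue

        orient, mate_chrom, mate_pos, mate_orient, insert = _parse_bnd_alt(rid, alt)
        mate_id = info.get("MATEID")
        if isinstance(mate_id, tuple):
            mate_id = mate_id[0]
        if mate_id is None or mate_id not in records:
            import warnings as _warnings
            _warnings.warn(f"record {rid}: dangling MATEID {mate_id!r}; demoted to single breakend")
            be = Breakend(rid, rec["chrom"], rec["pos"], orient, insert, homlen, asm, repclass)
            junctions.append(Junction(rid, be, None, jcn, jcn_low, jcn_high))
            seen.add(rid)
            continue

        mrec = records[mate_id]
        minfo = mrec["info"]
        masm = list(minfo.get("BEID", ())) if "BEID" in minfo else []
        be1 = Breakend(rid, rec["chrom"], rec["pos"], orient, insert, homlen, asm, repclass)
        be2 = Breakend(mate_id, mrec["chrom"], mrec["pos"], mate_orient, "",
                       int(minfo.get("HOMLEN", 0)), masm, minfo.get("REPCLASS"))
        base = rid[:-2] if rid.endswith(("_a", "_b", "_1", "_2")) else rid
        junctions.append(Junction(base, be1, be2, jcn, jcn_low, jcn_high))
        seen.update((rid, mate_id))
    return junctions


def _read_junctions_tsv(path: str | Path) -> list[Junction]:
    junctions = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {h: i for i, h in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")

            def get(col: str, default: str = ".") -> str:
                return f[idx[col]] if col in idx and idx[col] < len(f) else default

            jid = get("id")
            be1 = Breakend(
                jid + "_a", get("chrom1"), int(get("pos1")), int(get("orient1")),
                "" if get("insert1") == "." else get("insert1"),
                int(get("homlen", "0") or 0),
                [] if get("asm1") == "." else get("asm1").split(","),
                None if get("repeat1") == "." else get("repeat1"),
            )
            be2 = None
            if get("chrom2") != ".":
                be2 = Breakend(
                    jid + "_b", get("chrom2"), int(get("pos2")), int(get("orient2")),
                    "" if get("insert2") == "." else get("insert2"),
                    int(get("homlen", "0") or 0),
                    [] if get("asm2") == "." else get("asm2").split(","),
                    None if get("repeat2") == "." else get("repeat2"),
                )
            jcn = float(get("jcn", "1"))
            jl = get("jcn_low");  jh = get("jcn_high")
            junctions.append(Junction(
                jid, be1, be2, jcn,
                None if jl in (".", "") else float(jl),
                None if jh in (".", "") else float(jh),
            ))
    return junctions


def read_junctions(path: str | Path, dialect: str = "tsv") -> list[Junction]:
    """Read an SV junction callset.

    ``dialect="vcf_bnd"`` parses breakend-notation VCF (BND records merged by
    MATEID; unmated records become single breakends); ``"tsv"`` parses the
    documented junction table.
    """
    if dialect == "vcf_bnd":
        return _read_junctions_vcf(path)
    if dialect == "tsv":
        return _read_junctions_tsv(path)
    raise ValueError(f"unknown junction dialect {dialect!r}")


def write_junctions(junctions: Sequence[Junction], path: str | Path,
                    dialect: str = "tsv") -> None:
    if dialect == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(_TSV_HEADER) + "\n")
            for j in junctions:
                b1, b2 = j.start, j.end
                row = [
                    j.id, b1.chromosome, str(b1.position), str(b1.orientation),
                    b1.insert_sequence or ".", ",".join(b1.assembly_ids) or ".",
                    b1.repeat_class or ".",
                ]
                if b2 is None:
                    row += ["."] * 6
                else:
                    row += [
                        b2.chromosome, str(b2.position), str(b2.orientation),
                        b2.insert_sequence or ".", ",".join(b2.assembly_ids) or ".",
                        b2.repeat_class or ".",
                    ]
                row += [f"{j.jcn:g}", f"{j.jcn_low:g}", f"{j.jcn_high:g}",
                        str(b1.homology_length)]
                fh.write("\t".join(row) + "\n")
        return
    if dialect == "vcf_bnd":
        _write_junctions_vcf(junctions, path)
        return
    raise ValueError(f"unknown junction dialect {dialect!r}")


def _write_junctions_vcf(junctions: Sequence[Junction], path: str | Path) -> None:
    chroms = sorted({b.chromosome for j in junctions for b in j.breakends})
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">',
        '##INFO=<ID=JCN,Number=1,Type=Float,Description="Junction copy number">',
        '##INFO=<ID=JCNLO,Number=1,Type=Float,Description="JCN lower bound">',
        '##INFO=<ID=JCNHI,Number=1,Type=Float,Description="JCN upper bound">',
        '##INFO=<ID=HOMLEN,Number=1,Type=Integer,Description="Breakend homology length">',
        '##INFO=<ID=BEID,Number=.,Type=String,Description="Assembly phase-group ids">',
        '##INFO=<ID=REPCLASS,Number=1,Type=String,Description="Single-breakend repeat class">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="BND">',
    ]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    def info_str(j: Junction, b: Breakend, mate: Optional[str]) -> str:
        parts = [f"SVTYPE=BND", f"JCN={j.jcn:g}", f"JCNLO={j.jcn_low:g}", f"JCNHI={j.jcn_high:g}"]
        if mate:
            parts.append(f"MATEID={mate}")
        if b.homology_length:
            parts.append(f"HOMLEN={b.homology_length}")
        if b.assembly_ids:
            parts.append("BEID=" + ",".join(b.assembly_ids))
        if b.repeat_class:
            parts.append(f"REPCLASS={b.repeat_class}")
        return ";".join(parts)

    for j in junctions:
        b1, b2 = j.start, j.end
        if b2 is None:
            ins = b1.insert_sequence
            alt = f"N{ins}." if b1.orientation == 1 else f".{ins}N"
            lines.append("\t".join([b1.chromosome, str(b1.position), f"{j.id}_b1", "N",
                                    alt, ".", "PASS", info_str(j, b1, None)]))
            continue
        ins = b1.insert_sequence
        for this, other, this_id, other_id, this_ins in (
            (b1, b2, f"{j.id}_1", f"{j.id}_2", ins),
            (b2, b1, f"{j.id}_2", f"{j.id}_1", ins),
        ):
            bracket = "[" if other.orientation == -1 else "]"
            remote = f"{bracket}{other.chromosome}:{other.position}{bracket}"
            if this.orientation == 1:
                alt = f"N{this_ins}{remote}"
            else:
                alt = f"{remote}{this_ins}N"
            lines.append("\t".join([this.chromosome, str(this.position), this_id, "N",
                                    alt, ".", "PASS", info_str(j, this, other_id)]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# copy-number I/O
# ---------------------------------------------------------------------------

def read_copy_segments(path: str | Path) -> CopyNumberProfile:
    """Read an allele-specific segmented copy-number table.

    Expects tab-separated columns ``chromosome, start, end, copyNumber,
    minorAlleleCopyNumber``; validates per-chromosome coverage and non-overlap.
    """
    segments = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {h: i for i, h in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            segments.append(CopyNumberSegment(
                f[idx["chromosome"]], int(f[idx["start"]]), int(f[idx["end"]]),
                float(f[idx["copyNumber"]]), float(f[idx["minorAlleleCopyNumber"]]),
            ))
    return CopyNumberProfile(segments)


def write_copy_segments(profile: CopyNumberProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tstart\tend\tcopyNumber\tminorAlleleCopyNumber\n")
        for s in profile.all_segments():
            fh.write(f"{s.chromosome}\t{s.start}\t{s.end}\t{s.cn_total:g}\t{s.cn_minor:g}\n")


def read_karyotype(path: str | Path) -> Karyotype:
    """Read a karyotype table: chromosome, length, centromere_start,
    centromere_end (tab-separated with header)."""
    chroms = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            name, length, cs, ce = line.rstrip("\n").split("\t")[:4]
            chroms.append(Chromosome(name, int(length), int(cs), int(ce)))
    return Karyotype(chroms)


def write_karyotype(karyotype: Karyotype, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tlength\tcentromere_start\tcentromere_end\n")
        for c in karyotype.chromosomes.values():
            fh.write(f"{c.name}\t{c.length}\t{c.centromere_start}\t{c.centromere_end}\n")


# ---------------------------------------------------------------------------
# gene-model I/O
# ---------------------------------------------------------------------------

def _read_gene_model_tsv(path: str | Path) -> GeneModelCollection:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"coding_start": "object", "coding_end": "object"})
    genes = []
    for (gene, chrom, strand), gdf in df.groupby(["gene", "chromosome", "strand"], sort=False):
        transcripts = []
        for tid, tdf in gdf.groupby("transcript", sort=False):
            rows = tdf.sort_values("exon_start")
            exon_coords = list(zip(rows.exon_start.astype(int), rows.exon_end.astype(int)))
            cs = rows.coding_start.iloc[0]
            ce = rows.coding_end.iloc[0]
            cs = None if (cs is None or str(cs) in (".", "nan")) else int(float(cs))
            ce = None if (ce is None or str(ce) in (".", "nan")) else int(float(ce))
            if not exon_coords:
                import warnings as _warnings
                _warnings.warn(f"transcript {tid} has no exons; skipped")
                continue
            tx_order = exon_coords if strand == "+" else exon_coords[::-1]
            phases = compute_end_phases(tx_order, strand, cs, ce)
            exons = [Exon(s, e, p) for (s, e), p in zip(tx_order, phases)]
            transcripts.append(Transcript(str(tid), exons, cs, ce))
        if transcripts:
            genes.append(Gene(str(gene), str(chrom), str(strand), transcripts))
    return GeneModelCollection(genes)


def _read_gene_model_gtf(path: str | Path) -> GeneModelCollection:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", disable_infer_genes=True,
                            disable_infer_transcripts=True, keep_order=True)
    genes = []
    for g in db.features_of_type("gene"):
        name = g.attributes.get("gene_name", g.attributes.get("gene_id", ["?"]))[0]
        transcripts = []
        for t in db.children(g, featuretype="transcript"):
            tid = t.attributes.get("transcript_id", ["?"])[0]
            exon_coords = sorted((e.start, e.end) for e in db.children(t, featuretype="exon"))
            if not exon_coords:
                import warnings as _warnings
                _warnings.warn(f"transcript {tid} has no exons; skipped")
                continue
            cds = sorted((c.start, c.end) for c in db.children(t, featuretype="CDS"))
            cs = cds[0][0] if cds else None
            ce = cds[-1][1] if cds else None
            tx_order = exon_coords if g.strand == "+" else exon_coords[::-1]
            phases = compute_end_phases(tx_order, g.strand, cs, ce)
            exons = [Exon(s, e, p) for (s, e), p in zip(tx_order, phases)]
            transcripts.append(Transcript(tid, exons, cs, ce))
        if transcripts:
            genes.append(Gene(name, g.seqid, g.strand, transcripts))
    return GeneModelCollection(genes)


def read_gene_model(path: str | Path, dialect: str = "tsv") -> GeneModelCollection:
    """Read a gene model (GTF with gene/transcript/exon/CDS features, or the
    simplified one-row-per-exon TSV); exon end phases are computed from the
    cumulative CDS length mod 3 in transcript orientation."""
    if dialect == "gtf":
        return _read_gene_model_gtf(path)
    if dialect == "tsv":
        return _read_gene_model_tsv(path)
    raise ValueError(f"unknown gene-model dialect {dialect!r}")


# ---------------------------------------------------------------------------
# base-pair consistency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsistencyViolation:
    chromosome: str
    boundary: int
    delta_cn: float
    explained: float
    residual: float


@dataclass
class ConsistencyReport:
    violations: list[ConsistencyViolation]
    tolerance: float

    @property
    def consistent(self) -> bool:
        return not self.violations


def validate_bp_consistency(junctions: Sequence[Junction], profile: CopyNumberProfile,
                            tolerance: float = 0.15) -> ConsistencyReport:
    """Check that every copy-number change is matched by oriented junction
    copy number.

    A breakend with orientation ``+1`` at position ``p`` explains a CN *drop*
    of its JCN crossing from ``<= p`` to ``> p`` (boundary ``p + 1`` in
    half-open segment coordinates); orientation ``-1`` at ``p`` explains a
    *rise* at boundary ``p``.  All segment boundaries and all breakend-implied
    boundaries are checked; residuals above ``tolerance`` are reported.
    """
    contrib: dict[tuple[str, int], float] = {}
    for j in junctions:
        for b in j.breakends:
            if b.orientation == 1:
                key = (b.chromosome, b.position + 1)
                contrib[key] = contrib.get(key, 0.0) - j.jcn
            else:
                key = (b.chromosome, b.position)
                contrib[key] = contrib.get(key, 0.0) + j.jcn

    check: set[tuple[str, int]] = set(contrib)
    for chrom in profile.by_chromosome:
        for b in profile.boundaries(chrom):
            check.add((chrom, b))

    violations = []
    for chrom, boundary in sorted(check):
        if boundary <= 1:
            continue
        segs = profile.segments(chrom)
        if not segs or boundary >= segs[-1].end:
            continue
        delta = profile.cn_at(chrom, boundary) - profile.cn_at(chrom, boundary - 1)
        explained = contrib.get((chrom, boundary), 0.0)
        residual = abs(delta - explained)
        if residual > tolerance:
            violations.append(ConsistencyViolation(chrom, boundary, delta, explained, residual))
    return ConsistencyReport(violations, tolerance)
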