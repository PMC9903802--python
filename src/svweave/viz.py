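"""Simplified per-cluster visualization.

A circular layout in plain SVG: breakends are placed around a circle with
the arc between adjacent breakends proportional to ``log10(distance + 10)``,
so kilobase and megabase structure are readable on one chart.  Tracks:
copy-number ticks, junction chords, chain-order labels, and gene/exon boxes
when gene annotations are supplied.  Output is deterministic for fixed input.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

from .chain import Chain
from .genome_model import CopyNumberProfile, Junction

__all__ = ["arc_weight", "layout_breakends", "render_cluster_svg"]

INTER_CHROM_GAP = 10_000_000   # notional distance between chromosome blocks


def arc_weight(distance: int) -> float:
    """Log-based position scaling: arc length between adjacent breakends is
    proportional to log10(distance + 10)."""
    return math.log10(distance + 10)


def layout_breakends(junctions: Sequence[Junction]) -> dict[str, float]:
    """Angle (radians) for every breakend, ordered by genome position with
    log-scaled gaps."""
    bnds = sorted((b for j in junctions for b in j.breakends),
                  key=lambda b: (b.chromosome, b.position, b.id))
    if not bnds:
        return {}
    weights = [arc_weight(INTER_CHROM_GAP)]   # opening gap closes the circle
    for prev, cur in zip(bnds, bnds[1:]):
        d = (cur.position - prev.position) if cur.chromosome == prev.chromosome \
            else INTER_CHROM_GAP
        weights.append(arc_weight(max(d, 0)))
    total = sum(weights)
    angles = {}
    acc = 0.0
    for b, w in zip(bnds, weights):
        acc += w
        angles[b.id] = 2 * math.pi * acc / total
    return angles


def render_cluster_svg(junctions: Sequence[Junction], chains: Sequence[Chain],
                       profile: Optional[CopyNumberProfile] = None,
                       gene_annotations: Optional[dict] = None,
                       out_path: Optional[str | Path] = None,
                       size: int = 600) -> str:
    """Render one cluster; returns the SVG text (and writes it when a path
    is given).  An empty cluster yields a placeholder figure."""
    cx = cy = size / 2
    r = size * 0.38
    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" height="{size}" '
             f'viewBox="0 0 {size} {size}">',
             f'<circle cx="{cx}" cy="{cy}" r="{r:.1f}" fill="none" stroke="#999"/>']
    angles = layout_breakends(junctions)

    def xy(angle: float, radius: float) -> tuple[float, float]:
        return (cx + radius * math.cos(angle - math.pi / 2),
                cy + radius * math.sin(angle - math.pi / 2))

    if not angles:
        parts.append(f'<text x="{cx}" y="{cy}" text-anchor="middle" '
                     f'font-size="14">empty cluster</text>')
    else:
        # copy-number ticks just outside the circle
        if profile is not None:
            for j in junctions:
                for b in j.breakends:
                    cn = profile.cn_at(b.chromosome, b.position)
                    x1, y1 = xy(angles[b.id], r + 4)
                    x2, y2 = xy(angles[b.id], r + 4 + min(cn, 40) * 2)
                    parts.append(f'<line x1="{x1:.1f}" y1="{y1:.1f}" x2="{x2:.1f}" '
                                 f'y2="{y2:.1f}" stroke="#2a7" stroke-width="2"/>')
        # junction chords
        for j in junctions:
            if j.end is None:
                x, y = xy(angles[j.start.id], r)
                parts.append(f'<circle cx="{x:.1f}" cy="{y:.1f}" r="3" fill="#c33"/>')
                continue
            x1, y1 = xy(angles[j.start.id], r)
            x2, y2 = xy(angles[j.end.id], r)
            parts.append(f'<path d="M {x1:.1f} {y1:.1f} Q {cx:.1f} {cy:.1f} '
                         f'{x2:.1f} {y2:.1f}" fill="none" stroke="#55c"/>')
        # chain order labels
        for ch in chains:
            for i, ln in enumerate(ch.links):
                mid = (angles[ln.breakend_a.id] + angles[ln.breakend_b.id]) / 2
                x, y = xy(mid, r * 0.82)
                parts.append(f'<text x="{x:.1f}" y="{y:.1f}" font-size="9" '
                             f'text-anchor="middle">{ch.id}.{i + 1}</text>')
        # breakend markers and gene boxes
        for j in junctions:
            for b in j.breakends:
                x, y = xy(angles[b.id], r)
                parts.append(f'<circle cx="{x:.1f}" cy="{y:.1f}" r="2" fill="#333"/>')
                for a in (gene_annotations or {}).get(b.id, []):
                    gx, gy = xy(angles[b.id], r + 34)
                    parts.append(f'<rect x="{gx - 14:.1f}" y="{gy - 7:.1f}" width="28" '
                                 f'height="10" fill="#fc6" stroke="#a80"/>')
                    parts.append(f'<text x="{gx:.1f}" y="{gy + 1:.1f}" font-size="7" '
                                 f'text-anchor="middle">{a.gene}</text>')
    parts.append("</svg>")
    svg = "\n".join(parts)
    if out_path is not None:
        Path(out_path).write_text(svg)
    return svg
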