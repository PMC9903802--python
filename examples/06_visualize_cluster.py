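"""Render a complex cluster as a circular SVG.

Simulates a 15-break chromothripsis event and draws its cluster: breakends
around a circle with log-scaled gaps (arc length proportional to
log10(distance + 10), so kilobase and megabase structure share one chart),
junctions as chords, copy number as radial ticks, and chain-order labels.
"""

from pathlib import Path

from svweave import run_sample
from svweave.simulate import EventSpec, simulate_sample
from svweave.viz import render_cluster_svg

sample = simulate_sample([EventSpec("chromothripsis", {"n_breaks": 15})], seed=6)
result = run_sample(sample.junctions, sample.profile, sample.karyotype)

biggest = max(result.clusters, key=lambda c: len(c.junction_ids))
by_id = {j.id: j for j in sample.junctions}
out = Path("scratch") if Path("scratch").is_dir() else Path(".")
path = out / "cluster.svg"
render_cluster_svg([by_id[j] for j in biggest.junction_ids],
                   result.chains_by_cluster[biggest.id],
                   sample.profile, out_path=path)
print(f"cluster {biggest.id}: {len(biggest.junction_ids)} junctions, resolved "
      f"{result.resolutions[biggest.id].label}")
print(f"wrote {path}")
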