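"""Telling circular from linear amplification.

An ecDNA circle shows high-JCN junctions that chain into a closed loop next
to low-copy flanks; a breakage-fusion-bridge cascade leaves a ladder of
same-orientation foldback inversions whose amplification is explained by
2^n_foldbacks x base copy number.  Both are simulated and classified.
"""

from svweave import run_sample
from svweave.simulate import EventSpec, simulate_sample

for kind, params in [("ecdna", {"n_segments": 3, "copies": 23}),
                     ("bfb", {"n_cycles": 4})]:
    sample = simulate_sample([EventSpec(kind, params)], seed=3)
    result = run_sample(sample.junctions, sample.profile, sample.karyotype,
                        sample.gene_model, sample.knowledgebase)
    res = max(result.resolutions.values(),
              key=lambda r: len(result.clusters[r.cluster_id].junction_ids))
    print(f"--- simulated {kind} ---")
    print(f"resolved: {res.label}   mechanism: {res.mechanism}")
    if res.ecdna is not None:
        e = res.ecdna
        print(f"loop jcn {e.loop_jcn:g}  closure {e.closure:.2f}  "
              f"flank cn {e.flank_cn:g}  foldbacks {e.foldback_count}  "
              f"foldback-explained bound {e.foldback_bound:g}")
    print()
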