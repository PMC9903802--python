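"""Gene impact: chained fusions and homozygous disruptions.

Builds three toy rearrangements against the bundled two-gene model:
(1) a direct translocation fusing FUS5 intron 1 to FUS3 intron 10 (phases
match, so the fusion is in frame); (2) the same fusion routed through a
500-base genomic shard on a third chromosome (a chained fusion with two
hops); (3) a reciprocal translocation through a tumor suppressor at copy
number 2 — both derivatives truncate the gene, so no intact copy remains
although no exonic base loses copy number (a homozygous disruption).
"""

from svweave.benchmarks import fusion_toy_study, homdisruption_toy_study

f = fusion_toy_study()
print("direct fusion:   links =", f["direct_links"],
      " in frame =", bool(f["direct_in_frame"]))
print("phase mismatch:  in frame =", bool(f["phase_mismatch_in_frame"]))
print("chained fusion:  links =", f["chained_links"],
      " in frame =", bool(f["chained_in_frame"]))

d = homdisruption_toy_study()
print("\nreciprocal TRL through TSG1 at CN 2:")
print(f"  min exonic CN        = {d['reciprocal_min_exonic_cn']:g}")
print(f"  undisrupted copies   = {d['reciprocal_undisrupted_copies']:g}")
print(f"  homozygous disruption: {bool(d['reciprocal_homozygous'])}")
print(f"single TRL homozygous: {bool(d['single_trl_homozygous'])}")
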