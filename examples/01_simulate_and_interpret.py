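"""Simulate a rearranged tumor genome and interpret it end to end.

Scripts four events (a deletion, a reciprocal translocation, an ecDNA
circle, and a LINE insertion) onto a 4-chromosome toy genome, then runs
annotation -> clustering -> chaining -> classification and prints what each
cluster was resolved as.  The resolved labels should match the scripted
event classes.
"""

from svweave import run_sample
from svweave.simulate import EventSpec, simulate_sample

sample = simulate_sample(
    [EventSpec("simple_del"), EventSpec("recip_trl"),
     EventSpec("ecdna", {"copies": 23}), EventSpec("line_insertion")],
    seed=7)

result = run_sample(sample.junctions, sample.profile, sample.karyotype,
                    sample.gene_model, sample.knowledgebase)

print(f"{len(sample.junctions)} junctions from {len(sample.truth)} scripted events")
print(f"callset base-pair consistent: {result.consistency.consistent}\n")
print(f"{'cluster':>7} {'junctions':>9} {'resolved':>14} {'mechanism':>12}")
for cl in result.clusters:
    res = result.resolutions[cl.id]
    print(f"{cl.id:>7} {len(cl.junction_ids):>9} {res.label:>14} {res.mechanism:>12}")

print("\nscripted truth:", ", ".join(ev.expected_label for ev in sample.truth))
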