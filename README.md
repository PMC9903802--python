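# svweave

Interpretation of somatic structural variation in tumor whole-genome
sequencing.  Given a structural-variant junction callset (breakend-notation
VCF or a junction table) and a base-pair-consistent, allele-specific
segmented copy-number profile, `svweave`:

1. **annotates** each breakend with geometric and genomic context — arm,
   foldback-inversion membership, LOH / homozygous-deletion /
   high-major-allele run bounding, fragile sites, LINE-source and poly-A
   evidence, cis/trans phasing of proximate facing breakends;
2. **clusters** junctions into rearrangement events via independent rules
   (proximity < 5 kb, copy-number run bounding, common arms of
   translocations, overlap of inversions and > 1 Mb DEL/DUPs, same-arm
   foldbacks), with mobile-element junctions gated to local rules only;
3. **chains** each cluster's facing breakends into predicted derivative
   chromosomes under allele-specific copy-number constraints — a traversal
   may never allocate more copies than the segment has, may not cross a
   homozygous deletion, and loops without a centromere are only admitted as
   extrachromosomal-DNA candidates;
4. **classifies** every cluster: simple DEL/DUP, reciprocal
   inversion/translocation/duplication, *synthetic* events (a simple event
   interrupted by < 1 kb templated "genomic shards"), LINE insertions (with
   target-site duplication and partnered transductions), processed
   pseudogene insertions, ecDNA / double minutes, BFB-like ladders, and
   COMPLEX (≥ 3 junctions);
5. **predicts gene impact**: transcript-context annotation, DNA-level fusion
   calling on the chained derivative (including multi-junction *chained*
   fusions, with intron-phase frame logic), gene disruptions and
   **homozygous disruptions** (no intact copy although every exonic base
   keeps copy number), IG-enhancer rearrangements, driver–cluster matching,
   and a cohort-level Poisson enrichment test (BH-corrected, q < 0.1).

A scripted-genome **simulator** is a first-class component: events are
applied to explicit derivative-chromosome walks and the callset (junctions
with JCN, allele-specific CN segments) is derived mechanically from the
walks, so junctions and copy number are consistent by construction and
every stage is testable without external data.

## Core quantities

* A **breakend** is one side of a double-strand-break junction: position
  *p*, orientation *o* ∈ {+1, −1} (+1 ⇔ retained sequence extends toward
  lower coordinates).  A junction of two breakends on one chromosome is a
  DEL when (+1 lower, −1 higher), DUP when (−1, +1), INV when orientations
  match; across chromosomes it is a TRL; an unmated record is a single
  breakend (SGL).
* **JCN** (junction copy number) is the number of derivative-chromosome
  copies using a junction.  At every copy-number segment boundary,
  ΔCN must equal the oriented sum of breakend JCNs
  (`validate_bp_consistency`).
* The **ecDNA heuristic** requires a closed (or predominantly closed,
  score ≥ 0.5) chain with loop JCN ≥ 5, ≥ 2.3× the flanking copy number,
  and above what foldbacks could explain (2ⁿ × base CN) plus non-loop
  junctions feeding the region.  High amplification is JCN ≥ 8.
* **Enrichment**: with genome-wide rate r = total hom-disruptions / total
  gene length, gene g has λ = r·L(g), p = P(X ≥ obs | Poisson(λ)),
  q = Benjamini–Hochberg; q < 0.1 is reported.

## Worked example

```python
from svweave import run_sample
from svweave.simulate import EventSpec, simulate_sample

sample = simulate_sample(
    [EventSpec("simple_del"), EventSpec("recip_trl"),
     EventSpec("ecdna", {"copies": 23}), EventSpec("line_insertion")],
    seed=7)
result = run_sample(sample.junctions, sample.profile, sample.karyotype,
                    sample.gene_model, sample.knowledgebase)
```

prints (via `examples/01_simulate_and_interpret.py`):

```
8 junctions from 4 scripted events
callset base-pair consistent: True

cluster junctions       resolved    mechanism
      0         2      RECIP_TRL         none
      1         3  DOUBLE_MINUTE        ecDNA
      2         1            DEL         none
      3         2           LINE         none

scripted truth: DEL, RECIP_TRL, DOUBLE_MINUTE, LINE
```

Each scripted event is recovered: the reciprocal translocation's two
junctions cluster by proximity and resolve from their opposed breakends;
the three JCN-23 circle junctions chain into a closed loop flagged ecDNA
(loop JCN 23 vs flanking CN 2); the LINE insertion is recognized from its
poly-A single-breakend pair with a 16-base target-site duplication.

The `examples/` directory holds one short script per capability
(chromothripsis orientation ratios, ecDNA vs BFB, chained fusions and
homozygous disruptions, Poisson enrichment, cluster SVG rendering).  A thin
CLI mirrors the library: `svweave simulate`, `svweave run`,
`svweave enrich`, `svweave viz`; table schemas are in `docs/formats.md`.

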