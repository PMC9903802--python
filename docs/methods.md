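# Methods

## Model and coordinates

Breakends are 1-based genomic positions with orientation +1 when the
retained derivative sequence continues toward lower coordinates (the VCF
`t[p[` side) and −1 toward higher.  Copy-number segments are half-open
`[start, end)` so segment arithmetic is gap-free while breakend positions
match VCF.  A breakend with orientation +1 at position *p* explains a copy
drop crossing from ≤ *p* to > *p* (boundary *p*+1); −1 explains a rise at
*p*.  `validate_bp_consistency` checks every segment boundary and every
breakend-implied boundary: |ΔCN − Σ oriented JCN| ≤ tolerance.  The default
tolerance is 0.15 copies for real caller output, where copy-number fits are
noisy; the simulator is exact, so its output is validated at 0.01 and the
test suite uses that value.

Loss of heterozygosity is minor-allele CN < 0.5; homozygous deletion is
total CN < 0.5; high-major-allele regions have major CN ≥ ploidy + 2
(ploidy configurable, default 2).  These thresholds anchor both annotation
(run bounding) and clustering; they are conventions for what "effectively
zero / markedly amplified" means on a continuous CN scale, not fitted
values.

## Annotation

Foldback inversions are same-orientation breakend pairs ≤ 5,000 bases
apart, either within one inversion junction or across two junctions that
share an assembly phase group (a chained foldback).  The distance default
matches the clustering proximity scale.  Poly-A evidence is a window of
≥ 11 bases that is ≥ 90 % A (or T): the common retrotransposition
heuristic.  A locus becomes a *suspected* LINE source when ≥ 2 junctions
anchored within 5 kb each have a remote partner carrying a poly-A insert;
singleton poly-A junctions are too error-prone to promote.  Facing-pair
phasing uses assembly labels only (cis = shared label, trans = disjoint
labels on both sides); the signed facing distance is negative when the
breakends overlap, i.e. the rearrangement duplicated its target site.

## Clustering

Five independent rule families are implemented: strict < 5 kb proximity;
merging the two junctions whose breakends delimit an LOH, homozygous
deletion, or high-major-allele run; common arms at both ends of two
translocations; cross-overlap of inversions (any length) and DEL/DUP
variants ≥ 1 Mb (lengths above 1 Mb are not normally found in simple
events); and all foldbacks on one chromosome arm.  The rule registry is
extensible and each rule can be disabled; further rules from the upstream
tool's full set are not reimplemented here and are documented as absent.
The partition is the transitive closure of the pairwise relation, so it is
independent of input order.

Two behaviors matter for specificity.  Junctions with mobile-element
evidence only ever merge through proximity, so LINE translocation scatter
cannot stitch unrelated loci into spurious complex events.  And the
common-arms rule runs as a second stage restricted to translocations still
unclustered after the local rules: a coherent shard-insertion pair must not
be absorbed into an unrelated translocation that happens to touch the same
two arms.  On a full karyotype (46 arms) the rule is almost always safe;
on the 4-chromosome test genome the restriction is what keeps the false
merge rate at zero.

## Chaining

Candidate links are facing pairs — a −1 breakend below a +1 breakend on
one chromosome, from different junctions of one cluster — whose interval
crosses no homozygous deletion.  A greedy loop links the best viable
candidate until none remain, with priority: (1) cis-assembled pairs,
(2) pairs that are the only viable partner for both breakends, (3) pairs
with no intervening breakend, (4) shorter traversal, (5) higher minimum
JCN, ties by coordinate.  This cascade is a design choice aimed at linking
each breakend to its most locally plausible neighbor.  Copy-number
constraints are enforced continuously: allocated JCN over any base never
exceeds its total CN, links require overlapping JCN uncertainty windows
(or an integer multiple, admitting foldback replication), and trans-phased
pairs are never traversed (they live on different derivative copies).
Chains may only close into a loop when the loop JCN reaches the ecDNA
candidate floor — derivative chromosomes without a centromere are
otherwise not permitted.  Foldback double-traversal is modeled only
through the integer-multiple JCN allowance; chains do not replicate
junction copies.  Unresolvable clusters yield partial chains rather than
errors: the prediction is representative, not guaranteed.

An exhaustive enumerator of all maximal consistent pairings
(`enumerate_all_maximal_pairings`) serves as a brute-force audit for
clusters of ≤ 6 junctions: the greedy result must always be a member of
its set and must equal it when the set is a singleton.

## Classification

Dispatch order: LINE evidence, pseudogene match, single-junction simple
types, two-junction resolution, ecDNA, COMPLEX (≥ 3 junctions), otherwise
INCOMPLETE; every cluster receives exactly one label.  Shard-mediated
synthetic reduction is attempted before the reciprocal patterns because a
sub-kilobase templated insertion mimics a reciprocal topology; traversed
intervals < 1,000 bases whose flanking junctions jump away are shards, and
removing them and fusing the free chain ends yields the notional simple
event.  Reciprocal duplications require facing overlap (≥ 1 base) at both
loci; reciprocal translocations have opposed breakends at both loci.

Pseudogene insertions: the cluster's deletions must match intron splice
boundaries of a single transcript within ±5 bases, with ≥ 2 and ≥ 80 % of
introns matched; flanking integration junctions (TRL/SGL) are tolerated in
the cluster because the caller sees the host-integration breakends too.

ecDNA calls need a closed or predominantly closed chain (closure score
≥ 0.5, defined as loop JCN over loop JCN plus the JCN of non-loop junctions
with breakends in the loop footprint), loop JCN ≥ 5 and ≥ 2.3× the flanking
copy number, and loop JCN above the foldback-explained bound
2^(n foldbacks) × base CN plus feeding junctions.  The three numeric
thresholds are tunable defaults.  High amplification is max JCN ≥ 8;
mechanism is ecDNA if the heuristic fired, else BFB-like given ≥ 1
foldback, else linear-unexplained.

## Gene impact

A breakend is annotated against every overlapped transcript (plus a 100 kb
upstream window for fusion 5′ context; 10 kb for disruption annotation).
Intron phase is the end phase of the preceding exon in transcript
orientation; non-coding context (−1) only fuses to −1.  A junction confined
to a single intron is non-disruptive: the exon chain survives.

Fusions walk each derivative chain from every promoter-retaining 5′
context across up to 4 junctions to a correctly oriented 3′ context,
rejecting candidates whose transcript is cut by a further chain breakend
before its retained end; frame requires equal exit/entry phases.
Same-chromosome promiscuous-partner candidates closer than 1 Mb are
flagged read-through-like and not reported, since such pairs can arise
from transcription rather than rearrangement.

Homozygous disruptions: undisrupted copies = min exonic total CN − Σ JCN
of the transcript's disruptive junctions, floored at zero; a call requires
min exonic CN ≥ 0.5 (not homozygously deleted) and undisrupted < 0.5.
This per-gene subtraction treats each disruptive junction as removing its
JCN from the pool of intact copies — exact for reciprocal pairs and tandem
duplications (the motivating patterns), conservative (over-counting
disruption) when many breaks hit the same derivative copy, which real
phasing data would be needed to resolve.

Enrichment: background rate = cohort hom-disruption count / summed gene
length; per-gene λ = rate × length; upper-tail Poisson p via
`scipy.stats.poisson.sf`; Benjamini–Hochberg q with reporting at q < 0.1.

## Simulator

Every event mutates an explicit derivative representation: one walk
(ordered, oriented reference segments with optional novel insert text) per
chromosome per parental allele, plus circular walks with a multiplicity
for episomes.  Emission derives junctions as non-reference adjacencies
(JCN = derivative copies using the adjacency; adjacencies with inserts
longer than 30 bases become single-breakend pairs, mirroring unmappable
insertions) and the CN profile as per-base coverage split by allele.
Consistency between junctions and copy number therefore holds by
construction — which is precisely the property of upstream caller output
the package assumes.

Default study conditions: 4 chromosomes of 50 Mb with centromeres at
20 Mb; all events on one parental allele; events placed at disjoint
reserved loci with 300 kb spacing, 2 Mb from telomeres and centromere.
Simple DEL/DUP lengths are log-uniform 10–100 kb; reciprocal inversions
50 kb–2 Mb; reciprocal-duplication overlaps 20–500 kb; shards 100–900
bases; chromothripsis shatters a 10 Mb interval at 30 breaks with
fragment retention 0.95 (chosen so a 30-break event yields ≈ 30 junctions,
matching the event's nominal size; lost fragments still appear as LOH
holes at lower retention); BFB runs 4 cycles, appending the reversed,
bridge-clipped walk each cycle so the most distal retained region reaches
2ⁿ copies of the rearranged allele (2ⁿ + 1 total against the intact
homolog) with one foldback per cycle at JCN 2^(n−j) and an unhealed
terminal single breakend; ecDNA circles carry 3 segments at 23 copies
(loop CN 23 + 2, formed copy-neutrally without host excision); LINE
insertions duplicate a 16-base target site and insert literal poly-A text
(length 60, or 20 after a transduced fragment sourced ≤ 5 kb downstream
of the source element); pseudogene insertions splice the 16 exons of the
bundled donor transcript into a host site, emitting 15 intron-boundary
deletions plus two integration translocations.

What the simulator does *not* model: read-level noise, mapping artifacts,
breakend homology beyond a stored length, subclonal copy number, multi-hit
overlap of events at one locus, or real repeat sequence (LINE content is
poly-A text only).  Passing the recovery suites therefore demonstrates the
interpretation logic under clean, consistent callsets — the regime the
upstream caller pair is designed to approximate — not robustness to
caller noise, which enters only through the optional Gaussian JCN jitter
(off by default).

## Numerical and degenerate-input choices

JCN uncertainty defaults to ±0.5 when bounds are absent.  Chain link
viability uses an ε of 1e−9 against allocation bounds.  Ties in the greedy
cascade break on genomic coordinate, making chaining deterministic; the
clustering partition is order-independent by construction.  Empty callsets
produce empty (header-only) tables with exit code 0; callsets failing
consistency are still interpreted, but the CLI exits non-zero and writes
the violation report.  Clusters that cannot chain consistently resolve
INCOMPLETE rather than erroring.  A chain containing a single breakend is
never closed (the missing mate is an open end).

## Known limitations

The clustering rule set covers the five enumerated families, not the full
production rule set of the upstream tool.  The two-break resolution matrix
implements the canonical reciprocal/synthetic topologies; rarer
configurations resolve INCOMPLETE.  Chained-fusion viability implements
the promoter-retention / termination / orientation subset of the full
viable-context table.  The chromothripsis orientation test has an inherent
finite-size bias: the two joins attaching the shattered block to its
flanks can never be DUP-type, so at 30 breaks the DUP:INV ratio converges
to ≈ 0.465 rather than 0.5; the 1:2 expectation is asymptotic in the
number of breaks.  The per-gene homozygous-disruption arithmetic
over-counts when multiple breaks disrupt the same derivative copy.
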