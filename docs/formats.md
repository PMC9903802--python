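# File formats

All inputs and outputs are plain tab-separated text (or VCF 4.2 for
junctions).  Missing values are `.`.

## Inputs

### Junction table (`--dialect tsv`)

One row per junction; single breakends leave the second-breakend columns
as `.`.

| column | meaning |
|---|---|
| `id` | junction identifier |
| `chrom1`, `pos1`, `orient1` | first breakend (1-based; orientation +1 = retained side toward lower coordinates) |
| `insert1`, `asm1`, `repeat1` | insert sequence, comma-separated assembly phase-group ids, repeat class |
| `chrom2`, `pos2`, `orient2`, `insert2`, `asm2`, `repeat2` | second breakend or `.` |
| `jcn`, `jcn_low`, `jcn_high` | junction copy number and uncertainty bounds (defaults ±0.5) |
| `homlen` | breakend homology length |

### Junction VCF (`--dialect vcf_bnd`)

Standard breakend notation: paired BND records linked by `MATEID`, insert
sequence inside the ALT, single breakends as `t.` / `.t`.  INFO keys used:
`JCN`, `JCNLO`, `JCNHI`, `HOMLEN`, `BEID` (assembly phase groups),
`REPCLASS` (single-breakend repeat class).  These key names are this
package's dialect; map your caller's equivalents onto them.

### Copy-number segments

`chromosome  start  end  copyNumber  minorAlleleCopyNumber` with half-open
`[start, end)` segments that must tile each chromosome without gaps or
overlap.

### Karyotype

`chromosome  length  centromere_start  centromere_end`.

### Gene model

Either Ensembl-style GTF (`gene`/`transcript`/`exon`/`CDS` features) or a
simplified TSV with one row per exon:
`gene  chromosome  strand  transcript  exon_start  exon_end  coding_start  coding_end`.

### Knowledgebase directory

One optional TSV per table (all with a header row):
`known_fusion_pairs.tsv` (five_prime, three_prime);
`promiscuous_partners.tsv` (gene, side ∈ {5P, 3P});
`fragile_sites.tsv` and `line_sources.tsv` (chromosome, start, end);
`ig_regions.tsv` (name, chromosome, start, end, required_orientation);
`driver_panel.tsv` (gene);
`pathogenic_exon_rearrangements.tsv` (gene, exon_start, exon_end, type).

## Output tables (`svweave run --out DIR`)

| file | columns |
|---|---|
| `svs_annotated.tsv` | junction, breakend, chromosome, position, orientation, sv_type, jcn, arm, is_foldback, flanks_loh, in_fragile_site, line_source, cluster |
| `clusters.tsv` | cluster, n_junctions, rules, resolved_type, n_shards, amplification_mechanism |
| `links.tsv` | cluster, chain, link, breakend_a, breakend_b, chromosome, start, end, allocated_jcn |
| `chains.tsv` | cluster, chain, closed, jcn, n_junctions, spans_centromere |
| `fusions.tsv` | gene_5p, transcript_5p, breakend_5p, gene_3p, transcript_3p, breakend_3p, links, in_frame, match, reportable |
| `disruptions.tsv` | gene, transcript, n_disruptive, disruptive_jcn, min_exonic_cn, undisrupted_copies, homozygous |
| `drivers.tsv` | gene, driver_type, clusters |
| `ig_events.tsv` | region, ig_breakend, partner_breakend, oncogene |

`run.log` echoes junction/cluster counts and the consistency verdict; on a
failed consistency check `consistency_violations.tsv` lists every boundary
with its ΔCN, the oriented JCN sum, and the residual, and the CLI exits
non-zero.
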