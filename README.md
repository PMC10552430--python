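# pangenewga

Pangene clustering from pairwise whole-genome alignments, with confirmation
of gene presence–absence variation (PAV) by spliced lift-over.

## The problem

When several assemblies of one species (or of closely related species,
ANI ≥ 95%) are independently annotated, the "same" gene carries a different
identifier in every genome, may be split into partial models, merged with a
neighbour, inverted, duplicated in tandem — or simply missing from one
annotation even though the sequence is intact. A *pangene* is a cluster of
gene models that occupy a homologous genomic location across assemblies.
Pangene sets describe the species' total coding potential, and they make
apparent PAV testable: is a gene really deleted in a genotype, or merely
unannotated?

`pangenewga` builds pangene clusters directly from whole-genome alignment
(WGA) evidence, so it is not biased toward any reference annotation, and it
uses the same alignments to lift gene models onto unannotated segments and
decide each PAV call.

## Method

1. **Cut** — per assembly, cDNA/CDS/peptide sequences are cut from
   FASTA + GFF3 (records of ≤ 100 bp are dropped); optionally geneless
   tracts > 1 Mbp are hard-masked for aligner-friendly input.
2. **Project** — pairwise PAF alignments (minimap2/GSAlign style, with
   `cg:Z` or `cs:Z` tags) are decomposed through their CIGAR strings into
   gap-free mapped segments; each gene body *g* of assembly B is projected
   through the segments into assembly A's coordinates, keeping projections
   that cover ≥ 50% of the gene body.
3. **Call collinear pairs** — a projected gene *b* and a target gene *a*
   are collinear iff they lie on the same strand after projection and
   `overlap ≥ 0.5·len(a)  OR  overlap ≥ 0.5·span(b)` (the "either feature"
   reciprocal-overlap rule). A projection that overlaps no gene pairs
   instead with the bare genomic segment, the substrate for lift-over.
4. **Cluster** — collinear pairs are merged greedily (largest overlap
   first) subject to a neighbour-distance constraint: two members from the
   same assembly may share a cluster only on one chromosome with at most
   N = 5 annotated genes between them. Clusters record occupancy
   (number of assemblies with ≥ 1 gene member), split/tandem/inverted
   member counts, and all isoform sequences.
5. **Classify & report** — clusters are classed core (all n genomes),
   soft-core (≥ ⌈0.95 n⌉), shell, or singleton; deliverables include a
   BED-like pangene matrix, POCS (percentage of conserved sequences) and
   ANI matrices, and sampled pan/soft-core/core growth curves.
6. **Check PAV** — for clusters pairing genes with bare segments, the
   consensus CDS isoforms (length-mode rule) are aligned to the segment
   with a spliced aligner (exact k-mer seeds, intron-tolerant chaining,
   GT-AG junction placement, micro-exon rescue). An absence call is
   rejected — i.e. the gene is declared present but unannotated — only
   when a complete open reading frame aligns end-to-end; the recovered
   model is emitted as a patch GFF3. Partial matches (e.g. a single
   surviving exon after a real deletion) are classified and rejected.

A bundled simulator generates families of annotated assemblies from a
common ancestor with planted SNPs, indels, deletions, inversions,
split/hidden annotations and tandem duplications — together with the
*exact* PAF alignments implied by its own edit history and a machine-readable
ground truth, so the whole protocol is testable without external aligners
or data downloads.

## Worked example

Simulate four assemblies (~50 genes, pairwise ANI ≈ 97.5%) with planted
events, then run the full pipeline:

```
pangenewga simulate --seed 3 --n-genes 50 --outdir sim
pangenewga run \
  --assembly A1:sim/A1.fna:sim/A1.gff3 --assembly A2:sim/A2.fna:sim/A2.gff3 \
  --assembly A3:sim/A3.fna:sim/A3.gff3 --assembly A4:sim/A4.fna:sim/A4.gff3 \
  --paf A1:A2:sim/A1-A2.paf --paf A1:A3:sim/A1-A3.paf --paf A1:A4:sim/A1-A4.paf \
  --paf A2:A3:sim/A2-A3.paf --paf A2:A4:sim/A2-A4.paf --paf A3:A4:sim/A3-A4.paf \
  --outdir out
```

The run prints its manifest, e.g.:

```
 "n_clusters": 50,
 "occupancy": {"core": 44, "softcore": 0, "shell": 6, "singleton": 0,
               "softcore_total": 44, "total": 50},
 "n_liftover_checks": 6
```

50 ancestral genes yield 50 pangene clusters: 44 core (present in all four
assemblies) and 6 shell. The 6 shell clusters are the planted PAV — five
partial gene deletions and one hidden (present-but-unannotated) gene — each
paired with a candidate genomic segment from the affected assembly.
`out/liftover_report.tsv` then shows six lift-over attempts: the hidden
gene is recovered with a full-coverage, zero-mismatch intact ORF
(`missing_gene_confirmed`, written to `out/patch.gff3` with the exact
planted exon coordinates), while the five true deletions align only their
surviving 3' exon and are `rejected` with ORF status `partial`.
`out/pangene_matrix.tsv` (BED-like pangene matrix), `out/pocs.tsv`,
`out/ani.tsv` and `out/growth_curves.tsv` complete the deliverables.

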