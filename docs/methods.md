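# Methods

## Scope and model

`pangenewga` defines pangenes operationally: two gene models from different
assemblies belong to the same pangene when their genomic intervals overlap
after one is projected into the other's coordinate system through a
pairwise whole-genome alignment, on the same strand. No sequence-similarity
clustering, phylogeny or protein comparison is involved; the approach
therefore assumes closely related assemblies (the regime it targets is
ANI ≥ 95%; nucleotide-level WGAs degrade below ~80–85% identity, where
protein-based orthology is the better tool).

All internal coordinates are 0-based half-open. GFF3 is read and written
1-based inclusive, BED/PAF 0-based half-open; conversion happens only at
file boundaries.

## Coordinate projection

A PAF record's CIGAR (ops `M/=/X/I/D`; `cs:Z` difference strings are
normalised to `=/X`) is decomposed into gap-free *mapped segments* — one
per maximal run of co-consuming ops. Within a segment the base mapping is
affine; for `-` strand records query coordinates are kept on the forward
strand and decrease as target coordinates increase. A gene body is
projected by intersecting it with the segments' query intervals and
mapping each intersected run; the reported interval is the span from first
to last projected base. Projections covering < 50% of the gene body
(`min_coverage`, configurable) are discarded. When segments place a gene
on several target chromosomes, the chromosome with the most covered bases
wins (ties lexicographic) and the ambiguity is logged.

Secondary alignments (`tp:A:S`) are dropped at parse time; no mapping
quality filter is applied by default. Each unordered assembly pair is
aligned once; the same segment set serves both projection directions with
query/target roles swapped, which is exact because segments are bijective.

## Collinear calling

Projected gene *b* vs annotated gene *a*: emit a pair iff same chromosome,
same strand after projection, and `overlap ≥ f·len(a)` **or**
`overlap ≥ f·span(b)` with f = 0.5 — the reciprocal-"either" overlap rule
(the bedtools `-f 0.5 -F 0.5 -e` semantics, with ≥ at the boundary). One
projected gene may pair with several consecutive targets; this is what
lets a full-length model claim both halves of a split annotation.
Projections that pair with no gene, but cover ≥ 50% of their source gene,
become gene↔segment pairs — unless the source gene already has a gene-gene
partner in that assembly, since segments exist to explain absences.
An optional homologous-chromosome filter keeps only alignments whose two
chromosome names yield identical regex captures (e.g. `^chr\d+H`);
unplaced scaffolds then never contribute collinearity, which is a known way
to lose genes sitting on `chrUn`-type sequences.

## Greedy clustering

Gene-gene pairs are processed in deterministic order: descending
`overlap_bp`, then member ids (the underlying greedy order is otherwise
arbitrary; fixing it makes runs reproducible). Clusters are merged
union-find style, refusing any merge that would violate the same-assembly
distance rule: any two members from one assembly must share a chromosome
with at most `max_neighbors` = 5 annotated genes between them (cluster
diameter, i.e. `max_rank − min_rank − 1 ≤ N`). A refused gene stays
available to other clusters; genes never paired become singletons, so the
clusters partition all genes. Clusters are named after their
reference-assembly member (lowest gene rank; lexicographic fallback;
`_2`-style suffixes on collision).

Structure flags per cluster:

* **split** — with the mode CDS length (most frequent; ties → longest) as
  the reference model, an assembly contributing k > 1 members whose summed
  CDS length is within 20% of the mode counts k−1 split models. The 20%
  tolerance is a package constant, configurable.
* **tandem** — multi-member assemblies not explained as splits count k−1
  tandem copies.
* **inverted** — strand evidence from pairwise alignments is relative, so
  members are 2-colored by pair parity (inverted pair ⇒ opposite groups)
  and the strictly smaller orientation group is flagged; a tie flags
  nothing. This reproduces "genes found inverted" relative to the cluster
  consensus orientation.

## Occupancy, matrices, growth curves

Occupancy counts assemblies with ≥ 1 *gene* member; segment members never
count. Classes: core (= n), soft-core (≥ ⌈0.95 n⌉; reported totals are
inclusive of core), singleton (= 1), shell (everything between). The
ceiling convention makes 19/20 genomes soft-core. POCS(A,B) =
100·(g_A+g_B)/(T_A+T_B), where g_X counts X's genes in clusters shared
with the partner and T_X all of X's clustered genes; the formula is echoed
in the run manifest because "percentage of conserved sequences" has no
single canonical definition. ANI is the alignment-length-weighted mean
identity over aligned columns (indels excluded) — an approximation to an
aligner's internal ANI estimator, and labelled as such. Growth curves use
seeded random permutations of assembly order (default 10) and report
mean ± sd of pan/soft-core/core sizes per prefix length.

## Spliced lift-over

Candidate missing genes are clusters that pair genes with bare segments.
Consensus CDS isoforms are those within 50% of the mode CDS length
(ties → longest); the rest are outliers. The segment is extracted with
1 kb flanking pads (terminal exons need context) and each consensus CDS is
aligned on the hinted sense strand by the built-in spliced aligner:

* exact 12-mer seeds, merged into maximal exact matches per diagonal;
* co-linear chaining with a gap cost that charges introns a small constant
  (target gaps ≥ 30 bp with little query gap) instead of a
  length-proportional penalty;
* micro-exon rescue: query stretches left unaligned at a junction or at
  either end (exons shorter than the seed cannot anchor) are placed by
  exact search in the intervening/flanking target, preferring positions
  with `AG..`/`..GT` splice context;
* junction placement shifted to GT-AG where sequence-ambiguous;
* within-exon counts (matches/mismatches/indels) from a global edlib
  alignment of the aligned query span against the spliced target sequence.

ORF classification of the spliced sequence: `intact` requires full query
coverage, start codon, terminal stop, length ≡ 0 (mod 3) and no internal
stop; otherwise `partial`, `not_multiple_of_3`, `premature_stop`, or
`no_alignment`. A missing-gene call is *confirmed* (verdict
`missing_gene_confirmed`, patch GFF emitted) only for an intact ORF with
query coverage 1.0 (configurable down to 0.95); everything else is
rejected with its reason. Split mode aligns consensus CDS across the span
of a multi-member assembly (`split_fix` iff intact end-to-end); merged mode
aligns two clusters' consensus within one long member's locus and requires
both to be intact and disjoint. By default lift-over runs for clusters
with occupancy ≥ n/2 (configurable), mirroring the practice of surveying
well-supported shell clusters. Patch GFF3 output carries
gene/mRNA/exon/CDS rows with computed CDS phases and provenance
attributes; rejected verdicts are never written.

An adapter that shells out to GMAP (`-t 1 -2 -z sense_force -n 1 -F`) can
replace the built-in aligner where GMAP is installed; it is untested glue
and off every tested path.

## Synthetic data generator

The generator emulates a family of annotated assemblies of one species:

* **Ancestor** — `n_genes` (default 50) multi-exon genes per family,
  CDS = exons, ATG…stop with GT-AG introns (introns 60–150 bp), separated
  by ~800 bp intergenic tracts; 1 chromosome, 4 assemblies by default.
* **Divergence** — per-assembly SNPs at `snp_rate` = 0.015/bp (two
  independent lineages ⇒ pairwise ANI ≈ 97%), small indels (1–10 bp) at
  `indel_rate` = 5·10⁻⁴ restricted to intergenic tracts so that
  unperturbed genes keep intact ORFs and exact coordinates. Splice-site
  dinucleotides and CDS termini are never mutated; the gene bodies of
  event-target genes are excluded from point mutation in *every* assembly
  so that event outcomes (e.g. zero-mismatch recovery of a hidden gene)
  are unambiguous.
* **Events** (all on non-reference assemblies, never overlapping): partial
  deletions (5' exons removed, annotation dropped, > 50% of the gene body
  left so a candidate segment survives — the classic partially deleted
  locus), a 2-gene inversion, a split annotation (record split at an
  intron; sequence untouched), a hidden gene (annotation dropped,
  sequence intact) and a tandem duplication (sequence-identical copy
  inserted downstream and annotated).
* **Alignments** — pairwise PAF is composed from the tracked per-base
  ancestor→derived coordinate maps, with `=`/`X` resolved against the
  actual sequences; single-sided gaps ≤ 50 bp are bridged as I/D ops,
  longer ones split records (as a real aligner would at structural
  variants); inversions yield `-` strand records; each tandem copy gets an
  extra record mapping the partner's gene interval onto the copy, since
  the copy is invisible to the ancestor-composed map but trivially
  alignable in reality.

What the generator does *not* emulate: repeat landscapes and transposons
(geneless masking is exercised only on plain spacer tracts), alternative
isoforms (one transcript per gene), indel polymorphism inside genes,
sequencing/assembly error, and annotation noise beyond the planted event
types. Passing tests therefore demonstrate the protocol's correctness on
its own rules and exact alignments — not robustness to noisy real-world
WGAs, where alignment quality dominates.

## Numerical and degenerate-input choices

Exact integer arithmetic throughout projection and overlap; the only
floating thresholds are the overlap/coverage fractions (compared with ≥)
and the 20% split tolerance. Empty inputs produce header-only files, not
errors. PAF records failing their CIGAR/coordinate invariants are rejected
per line with a count, never silently repaired. POCS/ANI cells without
evidence are NaN ("missing"), never 0. Cluster, matrix and report rows are
always emitted in sorted order; reruns with identical config and seed are
byte-identical.

## Problem sizes used in tests

The test suite and the acceptance script run on simulated families of 3–4
assemblies × 12–50 genes (~120 kb per genome), 1000 random CIGAR
alignments for the projection oracle and 100 random gene sets (up to
500 × 500) for the collinear-calling oracle; the full suite completes in
well under a minute. These sizes were chosen as the smallest at which
every planted phenomenon (PAV, inversion, split, hidden, tandem) is
present and separable.
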