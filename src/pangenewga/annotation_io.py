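"""Genome FASTA + GFF3 loading, sequence cutting and geneless-region masking.

All internal coordinates are 0-based half-open; GFF3 files are read and
written as 1-based inclusive, BED/PAF as 0-based half-open.  Conversion
happens only at file boundaries.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Assembly",
    "GeneModel",
    "Transcript",
    "SequenceRecord",
    "AnnotationError",
    "load_assembly",
    "cut_sequences",
    "mask_geneless",
    "cut_gdna",
    "wrap_fasta",
]

FASTA_WIDTH = 60

#: default minimum cDNA/CDS length (records of this length or shorter are dropped)
DEFAULT_MIN_LEN = 100

#: default minimum length of a geneless tract before it is hard-masked
DEFAULT_MIN_GENELESS = 1_000_000


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent FASTA/GFF3 input."""


@dataclass
class Transcript:
    """A transcript: sorted exons plus CDS segments, coordinates 0-based half-open."""

    transcript_id: str
    exons: list[tuple[int, int]]
    cds_segments: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds_segments = sorted(self.cds_segments)
        for (s1, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"({s1},{e1}) and ({s2},...)"
                )

    @property
    def cdna_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e, _ in self.cds_segments)


@dataclass
class GeneModel:
    """An annotated gene on a named chromosome."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)
    order_rank: int = -1
    assembly_id: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(f"gene {self.gene_id}: start >= end")
        if self.strand not in "+-":
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SequenceRecord:
    """A cut sequence (cdna/cds/pep/gdna) with its genomic source interval."""

    seq_id: str
    kind: str  # cdna | cds | pep | gdna
    sequence: str
    source_interval: tuple[str, int, int, str]  # chromosome, start, end, strand
    gene_id: str = ""
    transcript_id: str = ""
    assembly_id: str = ""
    flags: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Assembly:
    """An annotated assembly: chromosome sequences plus an ordered gene index."""

    assembly_id: str
    chromosomes: dict[str, str]
    gene_index: dict[str, list[GeneModel]]  # chromosome -> genes sorted by start
    genes_without_transcripts: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.assembly_id:
            raise AnnotationError("assembly_id must be non-empty")
        self._assign_ranks()

    def _assign_ranks(self) -> None:
        for chrom, genes in self.gene_index.items():
            genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
            for rank, g in enumerate(genes):
                if g.chromosome != chrom:
                    raise AnnotationError(
                        f"gene {g.gene_id} indexed under {chrom} but on {g.chromosome}"
                    )
                if g.chromosome not in self.chromosomes:
                    raise AnnotationError(
                        f"gene {g.gene_id} references unknown chromosome {g.chromosome}"
                    )
                g.order_rank = rank
                g.assembly_id = self.assembly_id

    def all_genes(self) -> Iterable[GeneModel]:
        for chrom in sorted(self.gene_index):
            yield from self.gene_index[chrom]

    def get_gene(self, gene_id: str) -> GeneModel:
        for g in self.all_genes():
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.gene_index.values())


# ---------------------------------------------------------------------------
# loading


def _read_fasta(path: str) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise AnnotationError(f"no sequences found in FASTA {path}")
    return seqs


def load_assembly(fasta_path: str, gff_path: str, assembly_id: str) -> Assembly:
    """Load one annotated assembly from FASTA + GFF3 files.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention.  Genes lacking transcripts are retained
    and listed in ``genes_without_transcripts``.
    """
    chromosomes = _read_fasta(fasta_path)

    with open(gff_path) as fh:
        text = fh.read()
    _validate_gff_lines(text, gff_path)

    try:
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # pragma: no cover - gffutils error classes vary
        raise AnnotationError(f"failed to parse GFF3 {gff_path}: {exc}") from exc

    gene_index: dict[str, list[GeneModel]] = {c: [] for c in chromosomes}
    no_tx: list[str] = []
    for gf in db.features_of_type("gene"):
        if gf.seqid not in chromosomes:
            raise AnnotationError(
                f"GFF3 {gff_path}: gene {gf.id} references chromosome "
                f"{gf.seqid!r} absent from FASTA"
            )
        transcripts = []
        for tf in db.children(gf, featuretype=("mRNA", "transcript"), order_by="start"):
            exons = [
                (e.start - 1, e.end)
                for e in db.children(tf, featuretype="exon", order_by="start")
            ]
            cds = [
                (c.start - 1, c.end, int(c.frame) if c.frame in "012" else 0)
                for c in db.children(tf, featuretype="CDS", order_by="start")
            ]
            if not exons:  # exon-less mRNA: treat its span as one exon
                exons = [(tf.start - 1, tf.end)]
            transcripts.append(Transcript(tf.id, exons, cds))
        gene = GeneModel(
            gene_id=gf.id,
            chromosome=gf.seqid,
            start=gf.start - 1,
            end=gf.end,
            strand=gf.strand if gf.strand in "+-" else "+",
            transcripts=transcripts,
        )
        for tr in transcripts:
            for s, e in tr.exons:
                if s < gene.start or e > gene.end:
                    raise AnnotationError(
                        f"transcript {tr.transcript_id} exon ({s},{e}) outside "
                        f"gene {gene.gene_id} [{gene.start},{gene.end})"
                    )
        if not transcripts:
            no_tx.append(gene.gene_id)
        gene_index[gene.chromosome].append(gene)

    return Assembly(assembly_id, chromosomes, gene_index, no_tx)


def _validate_gff_lines(text: str, path: str) -> None:
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise AnnotationError(
                f"malformed GFF line {lineno} in {path}: expected 9 columns, "
                f"got {len(cols)}"
            )
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError as exc:
            raise AnnotationError(
                f"malformed GFF line {lineno} in {path}: non-integer coordinates"
            ) from exc
        if start < 1 or end < start:
            raise AnnotationError(
                f"malformed GFF line {lineno} in {path}: bad interval {start}-{end}"
            )


# ---------------------------------------------------------------------------
# sequence cutting


def _splice(chrom_seq: str, intervals: list[tuple[int, int]], strand: str) -> str:
    seq = "".join(chrom_seq[s:e] for s, e in sorted(intervals))
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def cut_sequences(
    assembly: Assembly, min_len: int = DEFAULT_MIN_LEN
) -> list[SequenceRecord]:
    """Cut cDNA, CDS and peptide sequences for every transcript of every gene.

    cDNA is the splice of the exons, CDS the splice of the CDS segments (both
    reverse-complemented on '-' strand genes); the peptide is the CDS
    translation.  cDNA/CDS records with length <= ``min_len`` are dropped,
    each record kind filtered independently.  A CDS whose length is not a
    multiple of 3 yields a truncated peptide flagged ``not_multiple_of_3``;
    internal stops are retained as '*' and flagged ``internal_stop``.
    """
    records: list[SequenceRecord] = []
    for gene in assembly.all_genes():
        chrom_seq = assembly.chromosomes[gene.chromosome]
        for tr in gene.transcripts:
            base = f"{gene.gene_id}:{tr.transcript_id}:{assembly.assembly_id}"
            interval = (gene.chromosome, gene.start, gene.end, gene.strand)
            cdna = _splice(chrom_seq, tr.exons, gene.strand)
            if len(cdna) > min_len:
                records.append(
                    SequenceRecord(
                        base, "cdna", cdna, interval,
                        gene.gene_id, tr.transcript_id, assembly.assembly_id,
                    )
                )
            if not tr.cds_segments:
                continue
            cds = _splice(chrom_seq, [(s, e) for s, e, _ in tr.cds_segments], gene.strand)
            if len(cds) > min_len:
                rec = SequenceRecord(
                    base, "cds", cds, interval,
                    gene.gene_id, tr.transcript_id, assembly.assembly_id,
                )
                records.append(rec)
                flags: list[str] = []
                coding = cds
                if len(cds) % 3:
                    flags.append("not_multiple_of_3")
                    coding = cds[: len(cds) - len(cds) % 3]
                pep = str(Seq(coding).translate())
                if "*" in pep[:-1]:
                    flags.append("internal_stop")
                records.append(
                    SequenceRecord(
                        base, "pep", pep, interval,
                        gene.gene_id, tr.transcript_id, assembly.assembly_id,
                        flags=flags,
                    )
                )
    # deterministic output independent of GFF ordering
    records.sort(key=lambda r: (r.kind, r.seq_id))
    return records


# ---------------------------------------------------------------------------
# masking and gDNA cutting


def mask_geneless(
    assembly: Assembly, min_geneless: int = DEFAULT_MIN_GENELESS
) -> str:
    """Return FASTA text with geneless tracts longer than ``min_geneless`` N-masked.

    A geneless tract is a maximal interval overlapped by no gene body.  Bases
    overlapping any gene are never masked; sequence length is conserved.
    """
    out = io.StringIO()
    for chrom in sorted(assembly.chromosomes):
        seq = list(assembly.chromosomes[chrom])
        genes = assembly.gene_index.get(chrom, [])
        # merged gene-body cover
        cover: list[tuple[int, int]] = []
        for g in genes:
            if cover and g.start <= cover[-1][1]:
                cover[-1] = (cover[-1][0], max(cover[-1][1], g.end))
            else:
                cover.append((g.start, g.end))
        gaps: list[tuple[int, int]] = []
        prev = 0
        for s, e in cover:
            gaps.append((prev, s))
            prev = max(prev, e)
        gaps.append((prev, len(seq)))
        for s, e in gaps:
            if e - s > min_geneless:
                seq[s:e] = "N" * (e - s)
        out.write(f">{chrom}\n")
        out.write(wrap_fasta("".join(seq)))
    return out.getvalue()


def wrap_fasta(seq: str, width: int = FASTA_WIDTH) -> str:
    return "".join(seq[i : i + width] + "\n" for i in range(0, len(seq), width))


def cut_gdna(
    assembly: Assembly, interval: tuple[str, int, int, str]
) -> SequenceRecord:
    """Cut a genomic slice; reverse-complemented when strand is '-'."""
    chrom, start, end, strand = interval
    if chrom not in assembly.chromosomes:
        raise AnnotationError(f"unknown chromosome {chrom!r}")
    clen = len(assembly.chromosomes[chrom])
    if start < 0 or end > clen or start >= end:
        raise AnnotationError(
            f"interval {chrom}:{start}-{end} out of bounds; would clip to "
            f"{chrom}:{max(start, 0)}-{min(end, clen)}"
        )
    seq = assembly.chromosomes[chrom][start:end]
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    seq_id = f"{assembly.assembly_id}:{chrom}:{start}-{end}({strand})"
    return SequenceRecord(seq_id, "gdna", seq, interval, assembly_id=assembly.assembly_id)
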