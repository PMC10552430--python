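"""Projection of gene models across assemblies through WGA mapped segments,
and calling of collinear gene pairs / gene↔genomic-segment matches.

A gene from assembly B is collinear with a gene from assembly A when, after
projecting B's gene body into A's coordinates through the alignment blocks,
the two intervals overlap by at least half the length of either feature and
lie on the same strand.  Genes whose projection lands on unannotated
sequence are paired with the bare genomic segment instead, as lift-over
candidates.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional

from intervaltree import IntervalTree

from .annotation_io import Assembly, GeneModel
from .wga import MappedSegment, WgaAlignment

logger = logging.getLogger(__name__)

__all__ = [
    "Member",
    "ProjectedGene",
    "CollinearPair",
    "project_gene",
    "call_collinear_pairs",
    "call_gdna_matches",
    "restrict_homologous",
]

DEFAULT_OVERLAP_FRACTION = 0.5
DEFAULT_MIN_COVERAGE = 0.5


@dataclass(frozen=True)
class Member:
    """One side of a collinear pair: a gene, or a bare genomic segment."""

    id: str
    assembly: str
    chromosome: str
    start: int
    end: int
    strand: str

    @classmethod
    def from_gene(cls, gene: GeneModel) -> "Member":
        return cls(gene.gene_id, gene.assembly_id, gene.chromosome,
                   gene.start, gene.end, gene.strand)

    @classmethod
    def segment(cls, assembly: str, chromosome: str, start: int, end: int,
                strand: str) -> "Member":
        return cls(f"segment:{chromosome}:{start}-{end}", assembly, chromosome,
                   start, end, strand)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CollinearPair:
    """Evidence that two members occupy homologous genomic positions."""

    member_a: Member
    member_b: Member
    overlap_bp: int
    wga_algorithm: str = "simulated"
    inverted: bool = False
    pair_type: str = "gene-gene"

    def __post_init__(self) -> None:
        if self.overlap_bp <= 0:
            raise ValueError("overlap_bp must be positive")
        if self.pair_type not in ("gene-gene", "gene-gdna"):
            raise ValueError(f"bad pair_type {self.pair_type!r}")


@dataclass
class ProjectedGene:
    """A gene body transferred into another assembly's coordinates."""

    gene: GeneModel
    source_assembly: str
    target_assembly: str
    target_chromosome: str
    target_start: int
    target_end: int
    projected_strand: str
    covered_bp: int
    inverted: bool  # alignment strand was '-'
    ambiguous_chromosomes: list[str] = field(default_factory=list)

    @property
    def coverage_fraction(self) -> float:
        return self.covered_bp / self.gene.length

    @property
    def span(self) -> int:
        return self.target_end - self.target_start


def project_gene(
    gene: GeneModel,
    segments: list[MappedSegment],
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    target_assembly: str = "",
) -> Optional[ProjectedGene]:
    """Project one gene body through mapped segments onto the target assembly.

    The gene body is intersected with the query intervals of the segments;
    intersected bases map to target coordinates by within-segment offset
    (reversed for '-' segments).  Returns None when the covered fraction of
    the gene body falls below ``min_coverage``.  If segments on several
    target chromosomes cover the gene, the chromosome with the most covered
    bases wins (ties lexicographic) and the ambiguity is recorded.
    """
    # per-target-chromosome accumulation: covered bp, interval bounds, strand bp
    per_chrom: dict[str, dict] = {}
    for seg in segments:
        if seg.query_name != gene.chromosome:
            continue
        lo = max(gene.start, seg.query_start)
        hi = min(gene.end, seg.query_end)
        if lo >= hi:
            continue
        if seg.strand == "+":
            t_lo = seg.target_start + (lo - seg.query_start)
            t_hi = seg.target_start + (hi - seg.query_start)
        else:
            t_lo = seg.target_start + (seg.query_end - hi)
            t_hi = seg.target_start + (seg.query_end - lo)
        acc = per_chrom.setdefault(
            seg.target_name,
            {"bp": 0, "lo": t_lo, "hi": t_hi, "minus_bp": 0},
        )
        acc["bp"] += hi - lo
        acc["lo"] = min(acc["lo"], t_lo)
        acc["hi"] = max(acc["hi"], t_hi)
        if seg.strand == "-":
            acc["minus_bp"] += hi - lo
    if not per_chrom:
        return None
    best = sorted(per_chrom.items(), key=lambda kv: (-kv[1]["bp"], kv[0]))
    chrom, acc = best[0]
    ambiguous = [c for c, _ in best[1:]]
    if ambiguous:
        logger.info(
            "gene %s projects onto several chromosomes %s; keeping %s",
            gene.gene_id, [chrom] + ambiguous, chrom,
        )
    if acc["bp"] / gene.length < min_coverage:
        return None
    inverted = acc["minus_bp"] * 2 > acc["bp"]
    strand = gene.strand
    if inverted:
        strand = "-" if strand == "+" else "+"
    alignment = next(
        (s.alignment for s in segments if s.target_name == chrom and s.alignment),
        None,
    )
    target_assembly = target_assembly or (
        alignment.target_assembly if alignment else ""
    )
    return ProjectedGene(
        gene=gene,
        source_assembly=gene.assembly_id,
        target_assembly=target_assembly,
        target_chromosome=chrom,
        target_start=acc["lo"],
        target_end=acc["hi"],
        projected_strand=strand,
        covered_bp=acc["bp"],
        inverted=inverted,
        ambiguous_chromosomes=ambiguous,
    )


def call_collinear_pairs(
    projected: list[ProjectedGene],
    targets: Assembly,
    f: float = DEFAULT_OVERLAP_FRACTION,
    wga_algorithm: str = "simulated",
) -> list[CollinearPair]:
    """Call collinear gene pairs between projected genes and target genes.

    A pair is emitted when the projected span and the target gene body
    overlap by at least ``f`` times the length of *either* feature and the
    projected strand equals the target gene's strand.  One projected gene
    may pair with several target genes (split-gene support).  Pairs are
    returned as (target gene = member_a, projected source gene = member_b).
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, genes in targets.gene_index.items():
        tree = IntervalTree()
        for g in genes:
            tree[g.start:g.end] = g
        trees[chrom] = tree

    pairs: list[CollinearPair] = []
    for pg in projected:
        tree = trees.get(pg.target_chromosome)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(pg.target_start, pg.target_end),
                         key=lambda iv: (iv.begin, iv.data.gene_id)):
            a: GeneModel = iv.data
            overlap = min(a.end, pg.target_end) - max(a.start, pg.target_start)
            if overlap <= 0:
                continue
            if pg.projected_strand != a.strand:
                continue
            if overlap >= f * a.length or overlap >= f * pg.span:
                pairs.append(
                    CollinearPair(
                        Member.from_gene(a),
                        Member.from_gene(pg.gene),
                        overlap,
                        wga_algorithm=wga_algorithm,
                        inverted=pg.inverted,
                        pair_type="gene-gene",
                    )
                )
    return pairs


def call_gdna_matches(
    unpaired_projected: list[ProjectedGene],
    targets: Assembly,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    wga_algorithm: str = "simulated",
) -> list[CollinearPair]:
    """Pair genes whose projection produced no gene-gene pair with the bare
    projected genomic segment of the target assembly (lift-over candidates).
    """
    pairs: list[CollinearPair] = []
    for pg in unpaired_projected:
        if pg.coverage_fraction < min_coverage:
            continue
        seg = Member.segment(
            targets.assembly_id, pg.target_chromosome,
            pg.target_start, pg.target_end, pg.projected_strand,
        )
        pairs.append(
            CollinearPair(
                Member.from_gene(pg.gene), seg,
                pg.covered_bp,
                wga_algorithm=wga_algorithm,
                inverted=pg.inverted,
                pair_type="gene-gdna",
            )
        )
    return pairs


def restrict_homologous(
    alignments: list[WgaAlignment], regex: str
) -> list[WgaAlignment]:
    """Keep alignments whose query and target chromosome names yield the same
    regex capture (homologous-chromosome mode); unmatched names are dropped.
    """
    pat = re.compile(regex)
    kept: list[WgaAlignment] = []
    matched_any = False
    for aln in alignments:
        mq = pat.match(aln.query_name)
        mt = pat.match(aln.target_name)
        if mq is None or mt is None:
            continue
        matched_any = True
        if mq.group(0) == mt.group(0):
            kept.append(aln)
    if alignments and not matched_any:
        logger.warning("regex %r matched no chromosome name pair", regex)
    return kept
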