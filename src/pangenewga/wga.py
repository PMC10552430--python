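"""Pairwise whole-genome alignment records: PAF parsing, CIGAR decomposition
into gap-free mapped segments, alignment identity / ANI, and the collinear
evidence TSV (including TSV→PAF conversion for dotplots).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WgaAlignment",
    "MappedSegment",
    "PafError",
    "parse_paf",
    "parse_paf_with_report",
    "parse_cigar",
    "cs_to_cigar",
    "cigar_to_segments",
    "alignment_identity",
    "ani_matrix",
    "write_collinear_tsv",
    "read_collinear_tsv",
    "tsv_to_paf",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = set("M=XI")
_TARGET_OPS = set("M=XD")
_ALIGN_OPS = set("M=X")


class PafError(ValueError):
    """Raised for PAF records that cannot be interpreted."""


@dataclass
class WgaAlignment:
    """One PAF alignment record with CIGAR.

    Coordinates are 0-based half-open; for '-' strand records the query
    interval is given in forward-strand coordinates and the CIGAR describes
    the reverse-complemented query walked along the forward target, as in
    the PAF specification.
    """

    query_name: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_len: int
    target_start: int
    target_end: int
    cigar: str
    mapq: int = 60
    source_algorithm: str = "minimap2"
    query_assembly: str = ""
    target_assembly: str = ""

    def validate(self) -> None:
        ops = parse_cigar(self.cigar)
        qspan = sum(n for n, op in ops if op in _QUERY_OPS)
        tspan = sum(n for n, op in ops if op in _TARGET_OPS)
        if qspan != self.query_end - self.query_start:
            raise PafError(
                f"CIGAR query span {qspan} != stated "
                f"{self.query_end - self.query_start}"
            )
        if tspan != self.target_end - self.target_start:
            raise PafError(
                f"CIGAR target span {tspan} != stated "
                f"{self.target_end - self.target_start}"
            )

    @property
    def aligned_columns(self) -> int:
        return sum(n for n, op in parse_cigar(self.cigar) if op in _ALIGN_OPS)


@dataclass
class MappedSegment:
    """A gap-free block of an alignment: equal-length query/target intervals.

    For '+' segments query position ``q_start + i`` pairs with target
    ``t_start + i``; for '-' segments query ``q_end - 1 - i`` (forward
    strand) pairs with target ``t_start + i``.
    """

    query_name: str
    query_start: int
    query_end: int
    target_name: str
    target_start: int
    target_end: int
    strand: str
    alignment: Optional[WgaAlignment] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.query_end - self.query_start != self.target_end - self.target_start:
            raise PafError("mapped segment intervals differ in length")

    def __len__(self) -> int:
        return self.target_end - self.target_start

    def map_query_to_target(self, q: int) -> int:
        """Map one query position (forward strand) to its target position."""
        if not self.query_start <= q < self.query_end:
            raise ValueError(f"query position {q} outside segment")
        if self.strand == "+":
            return self.target_start + (q - self.query_start)
        return self.target_start + (self.query_end - 1 - q)

    def swapped(self) -> "MappedSegment":
        """The same block with query and target roles exchanged."""
        return MappedSegment(
            self.target_name, self.target_start, self.target_end,
            self.query_name, self.query_start, self.query_end,
            self.strand, self.alignment,
        )


# ---------------------------------------------------------------------------
# parsing


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise PafError(f"unparseable CIGAR {cigar!r}")
    return ops


def cs_to_cigar(cs: str) -> str:
    """Convert a minimap2 cs:Z difference string to an extended =/X CIGAR."""
    out: list[str] = []

    def push(n: int, op: str) -> None:
        if n <= 0:
            return
        if out and out[-1][-1] == op:
            prev = out.pop()
            n += int(prev[:-1])
        out.append(f"{n}{op}")

    i = 0
    while i < len(cs):
        c = cs[i]
        if c == ":":
            m = re.match(r":(\d+)", cs[i:])
            if not m:
                raise PafError(f"bad cs string at offset {i}")
            push(int(m.group(1)), "=")
            i += m.end()
        elif c == "*":
            if i + 3 > len(cs):
                raise PafError(f"bad cs substitution at offset {i}")
            push(1, "X")
            i += 3
        elif c in "+-":
            m = re.match(r"[+-]([A-Za-z]+)", cs[i:])
            if not m:
                raise PafError(f"bad cs indel at offset {i}")
            push(len(m.group(1)), "I" if c == "+" else "D")
            i += m.end()
        elif c == "~":  # intron op: not expected in genome-genome PAF
            raise PafError("cs '~' intron operation unsupported")
        else:
            raise PafError(f"bad cs string at offset {i}: {c!r}")
    return "".join(out)


def _parse_paf_line(line: str) -> WgaAlignment:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 12:
        raise PafError(f"expected >= 12 columns, got {len(cols)}")
    tags = {c.split(":", 1)[0]: c for c in cols[12:]}
    if "tp" in tags and tags["tp"].endswith(":S"):
        raise PafError("secondary alignment")
    if "cg" in tags:
        cigar = tags["cg"].split(":", 2)[2]
    elif "cs" in tags:
        cigar = cs_to_cigar(tags["cs"].split(":", 2)[2])
    else:
        raise PafError("no cg:Z or cs:Z tag")
    aln = WgaAlignment(
        query_name=cols[0],
        query_len=int(cols[1]),
        query_start=int(cols[2]),
        query_end=int(cols[3]),
        strand=cols[4],
        target_name=cols[5],
        target_len=int(cols[6]),
        target_start=int(cols[7]),
        target_end=int(cols[8]),
        cigar=cigar,
    )
    if aln.strand not in "+-":
        raise PafError(f"bad strand {aln.strand!r}")
    aln.mapq = int(cols[11])
    aln.validate()
    return aln


def parse_paf_with_report(path: str) -> tuple[list[WgaAlignment], list[str]]:
    """Parse a PAF file; return (alignments, rejection messages).

    Secondary alignments (tp:A:S), CIGAR-less lines and records whose CIGAR
    is inconsistent with the stated coordinates are rejected, one message
    per line.
    """
    alignments: list[WgaAlignment] = []
    rejected: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                alignments.append(_parse_paf_line(line))
            except PafError as exc:
                rejected.append(f"line {lineno}: {exc}")
    if rejected:
        logger.warning(
            "%s: rejected %d of %d PAF lines", path, len(rejected),
            len(rejected) + len(alignments),
        )
    return alignments, rejected


def parse_paf(path: str) -> list[WgaAlignment]:
    return parse_paf_with_report(path)[0]


# ---------------------------------------------------------------------------
# segment decomposition


def cigar_to_segments(aln: WgaAlignment) -> list[MappedSegment]:
    """Decompose an alignment into gap-free mapped segments.

    One segment per maximal run of co-consuming ops (M/=/X); I advances the
    query cursor only, D the target cursor only.  Query intervals of '-'
    strand segments are reported in forward-strand coordinates.  Segments
    are ordered along the target.
    """
    segments: list[MappedSegment] = []
    t = aln.target_start
    q = aln.query_end if aln.strand == "-" else aln.query_start
    run = 0  # current co-consuming run length

    def flush() -> None:
        nonlocal run
        if run == 0:
            return
        if aln.strand == "+":
            qs, qe = q - run, q
        else:
            qs, qe = q, q + run
        segments.append(
            MappedSegment(
                aln.query_name, qs, qe, aln.target_name, t - run, t,
                aln.strand, aln,
            )
        )
        run = 0

    for n, op in parse_cigar(aln.cigar):
        if op in _ALIGN_OPS:
            t += n
            q += n if aln.strand == "+" else -n
            run += n
        elif op == "I":
            flush()
            q += n if aln.strand == "+" else -n
        elif op == "D":
            flush()
            t += n
        else:
            raise PafError(f"unsupported CIGAR op {op!r}")
    flush()
    return segments


# ---------------------------------------------------------------------------
# identity and ANI


def alignment_identity(
    aln: WgaAlignment,
    query_seq: str | None = None,
    target_seq: str | None = None,
) -> float:
    """Percent identity over aligned columns (indels excluded).

    With =/X CIGARs no sequence is needed; plain M ops require both full
    chromosome sequences (forward strand) to resolve matches.
    """
    from Bio.Seq import Seq

    matches = mismatches = 0
    need_seq = any(op == "M" for _, op in parse_cigar(aln.cigar))
    if need_seq and (query_seq is None or target_seq is None):
        raise PafError("identity unresolved: M ops present and no sequences supplied")
    qsub = tsub = ""
    if need_seq:
        tsub = target_seq[aln.target_start : aln.target_end]
        qsub = query_seq[aln.query_start : aln.query_end]
        if aln.strand == "-":
            qsub = str(Seq(qsub).reverse_complement())
    qi = ti = 0
    for n, op in parse_cigar(aln.cigar):
        if op == "=":
            matches += n
            qi += n
            ti += n
        elif op == "X":
            mismatches += n
            qi += n
            ti += n
        elif op == "M":
            for k in range(n):
                if qsub[qi + k] == tsub[ti + k]:
                    matches += 1
                else:
                    mismatches += 1
            qi += n
            ti += n
        elif op == "I":
            qi += n
        elif op == "D":
            ti += n
    if matches + mismatches == 0:
        raise PafError("alignment has no aligned columns")
    return 100.0 * matches / (matches + mismatches)


def ani_matrix(
    alignments: dict[tuple[str, str], list[WgaAlignment]],
    assemblies: list[str],
) -> pd.DataFrame:
    """Length-weighted mean pairwise identity, as a symmetric percent table.

    ``alignments`` maps (target_assembly, query_assembly) pairs to their
    alignment lists.  Pairs with no alignments are left NaN (missing, not 0).
    The weighting by aligned columns approximates the ANI a whole-genome
    aligner would report.
    """
    mat = pd.DataFrame(np.nan, index=assemblies, columns=assemblies, dtype=float)
    np.fill_diagonal(mat.values, 100.0)
    for (a, b), alns in alignments.items():
        if not alns:
            continue
        weights = np.array([aln.aligned_columns for aln in alns], dtype=float)
        idents = np.array([alignment_identity(aln) for aln in alns])
        ani = float(np.average(idents, weights=weights))
        mat.loc[a, b] = ani
        mat.loc[b, a] = ani
    return mat


# ---------------------------------------------------------------------------
# collinear evidence TSV

TSV_COLUMNS = [
    "gene_id_A", "assembly_A", "chrom_A", "start_A", "end_A", "strand_A",
    "gene_id_B_or_segment", "assembly_B", "chrom_B", "start_B", "end_B",
    "strand_B", "overlap_bp", "wga_algorithm", "inverted_flag", "pair_type",
]

PAIR_TYPES = {"gene-gene", "gene-gdna"}


def write_collinear_tsv(pairs: Iterable, path: str) -> None:
    """Write collinear evidence rows (see :data:`TSV_COLUMNS`)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(TSV_COLUMNS) + "\n")
        for p in pairs:
            a, b = p.member_a, p.member_b
            row = [
                a.id, a.assembly, a.chromosome, str(a.start), str(a.end), a.strand,
                b.id, b.assembly, b.chromosome, str(b.start), str(b.end), b.strand,
                str(p.overlap_bp), p.wga_algorithm,
                "1" if p.inverted else "0", p.pair_type,
            ]
            fh.write("\t".join(row) + "\n")


def read_collinear_tsv(path: str) -> list:
    from .collinearity import CollinearPair, Member

    pairs: list[CollinearPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != len(TSV_COLUMNS):
                raise PafError(f"{path} line {lineno}: expected "
                               f"{len(TSV_COLUMNS)} columns, got {len(cols)}")
            if cols[15] not in PAIR_TYPES:
                raise PafError(f"{path} line {lineno}: unknown pair_type {cols[15]!r}")
            member_a = Member(cols[0], cols[1], cols[2], int(cols[3]), int(cols[4]), cols[5])
            member_b = Member(cols[6], cols[7], cols[8], int(cols[9]), int(cols[10]), cols[11])
            pairs.append(
                CollinearPair(
                    member_a, member_b, int(cols[12]), cols[13],
                    cols[14] == "1", cols[15],
                )
            )
    return pairs


def tsv_to_paf(tsv_path: str, out_path: str) -> int:
    """Convert gene-gene evidence rows to PAF lines for generic dotplot tools.

    Gene B supplies the query block and gene A the target block, with a
    dummy CIGAR of the overlap length; gene-gdna rows are skipped.  Returns
    the number of lines written.
    """
    pairs = read_collinear_tsv(tsv_path)
    n = skipped = 0
    with open(out_path, "w") as fh:
        for p in pairs:
            if p.pair_type != "gene-gene":
                skipped += 1
                continue
            a, b = p.member_a, p.member_b
            strand = "-" if p.inverted else "+"
            line = [
                b.chromosome, str(b.end), str(b.start), str(b.end), strand,
                a.chromosome, str(a.end), str(a.start), str(a.end),
                str(p.overlap_bp), str(max(a.end - a.start, b.end - b.start)),
                "60", f"cg:Z:{p.overlap_bp}M",
            ]
            fh.write("\t".join(line) + "\n")
            n += 1
    if skipped:
        logger.info("tsv_to_paf: skipped %d gene-gdna rows", skipped)
    return n
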