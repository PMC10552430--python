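"""Confirming or rejecting gene presence-absence by spliced lift-over.

Clusters that pair annotated genes with bare genomic segments from other
assemblies are candidates for overlooked gene models: the cluster's
consensus CDS sequences are aligned to the segment with a spliced aligner
and, when a complete open reading frame aligns end to end, the absence call
is rejected and a patch GFF model is proposed.  Split and merged
annotations are handled analogously by aligning consensus sequences across
the candidate loci.

The built-in spliced aligner seeds exact k-mers, chains them with a gap
cost that makes introns cheap, prefers GT-AG intron boundaries when the
junction placement is ambiguous, and refines the within-exon alignment with
edlib.  It is deliberately conservative: it reports the single best chain
on the hinted sense strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import edlib
from Bio.Seq import Seq

from .annotation_io import Assembly, SequenceRecord
from .clustering import PangeneCluster

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusSet",
    "SplicedAlignment",
    "LiftoverResult",
    "consensus_isoforms",
    "spliced_align",
    "check_cluster",
    "emit_patch_gff",
]

DEFAULT_OUTLIER_FRACTION = 0.5
DEFAULT_FLANK_PAD = 1000
DEFAULT_MIN_QUERY_COVERAGE = 1.0
SEED_K = 12
MIN_INTRON = 30
MAX_JUNCTION_SHIFT = 10

STOP_CODONS = {"TAA", "TAG", "TGA"}

CONFIRM_VERDICTS = {"missing_gene_confirmed", "split_fix", "merged_fix"}


@dataclass
class ConsensusSet:
    consensus_isoforms: list[SequenceRecord]
    outliers: list[SequenceRecord]
    mode_length: int


def consensus_isoforms(
    cluster: PangeneCluster, outlier_frac: float = DEFAULT_OUTLIER_FRACTION
) -> ConsensusSet:
    """Partition a cluster's CDS isoforms into consensus and outliers.

    The mode length is the most frequent CDS length (ties -> longest);
    isoforms within ``outlier_frac`` of the mode are consensus.
    """
    cds = cluster.sequences.get("cds", [])
    if not cds:
        raise ValueError(f"cluster {cluster.cluster_id}: no coding evidence")
    counts: dict[int, int] = {}
    for rec in cds:
        counts[len(rec)] = counts.get(len(rec), 0) + 1
    mode = max(counts, key=lambda L: (counts[L], L))
    consensus, outliers = [], []
    for rec in cds:
        (consensus if abs(len(rec) - mode) <= outlier_frac * mode else outliers).append(rec)
    return ConsensusSet(consensus, outliers, mode)


# ---------------------------------------------------------------------------
# spliced alignment


@dataclass
class SplicedAlignment:
    """A spliced alignment of a query onto a segment (segment coordinates)."""

    exon_blocks: list[tuple[int, int]]  # ascending, within the given sequence
    query_start: int
    query_end: int
    query_length: int
    matches: int
    mismatches: int
    insertions_bp: int
    deletions_bp: int
    strand: str
    spliced_seq: str = field(repr=False, default="")

    @property
    def query_coverage(self) -> float:
        return (self.matches + self.mismatches) / self.query_length


def _mem_anchors(query: str, target: str, k: int = SEED_K) -> list[tuple[int, int, int]]:
    """Maximal exact matches as (q, t, length), merged along diagonals."""
    index: dict[str, list[int]] = {}
    for t in range(len(target) - k + 1):
        index.setdefault(target[t : t + k], []).append(t)
    hits: dict[int, list[int]] = {}  # diagonal -> query positions
    for q in range(len(query) - k + 1):
        for t in index.get(query[q : q + k], ()):
            hits.setdefault(t - q, []).append(q)
    anchors: list[tuple[int, int, int]] = []
    for diag, qs in hits.items():
        qs.sort()
        run_start = prev = qs[0]
        for q in qs[1:] + [qs[-1] + 2]:
            if q == prev + 1:
                prev = q
                continue
            anchors.append((run_start, run_start + diag, prev - run_start + k))
            run_start = prev = q
    return anchors


def _chain(anchors: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Best-scoring co-linear chain; introns (large target gaps) are cheap."""
    anchors = sorted(anchors, key=lambda a: (a[0], a[1]))
    if len(anchors) > 400:  # repeat guard
        anchors = sorted(anchors, key=lambda a: -a[2])[:400]
        anchors.sort(key=lambda a: (a[0], a[1]))
    n = len(anchors)
    score = [0.0] * n
    back = [-1] * n
    for i, (qi, ti, li) in enumerate(anchors):
        score[i] = float(li)
        for j in range(i):
            qj, tj, lj = anchors[j]
            trim = max(0, qj + lj - qi, tj + lj - ti)
            if trim >= li or qj >= qi or tj >= ti:
                continue
            qgap = max(0, qi - (qj + lj))
            tgap = max(0, ti - (tj + lj))
            if tgap - qgap >= MIN_INTRON:
                cost = 8.0 + 0.2 * qgap  # intron
            else:
                cost = 4.0 + 0.3 * max(qgap, tgap)
            s = score[j] + (li - trim) - cost
            if s > score[i]:
                score[i] = s
                back[i] = j
    if not anchors:
        return []
    best = max(range(n), key=lambda i: score[i])
    chain = []
    i = best
    while i != -1:
        chain.append(anchors[i])
        i = back[i]
    chain.reverse()
    # trim residual overlaps between consecutive anchors
    out = [chain[0]]
    for q, t, l in chain[1:]:
        pq, pt, pl = out[-1]
        trim = max(0, pq + pl - q, pt + pl - t)
        if trim >= l:
            continue
        out.append((q + trim, t + trim, l - trim))
    return out


def _rescue_micro_exons(query: str, target: str,
                        blocks: list[list[int]]) -> None:
    """Place query bases left unaligned at junctions or ends as micro-exons.

    Exons shorter than the seed k-mer cannot anchor a chain; when the
    missing query stretch occurs verbatim inside the intervening (or
    flanking) target region it is inserted as its own exon block, candidate
    positions with AG../..GT splice context preferred.

    Blocks are [t_start, t_end, q_start, q_end] and stay sorted.
    """

    def find(qseq: str, lo: int, hi: int, near: int) -> Optional[int]:
        if not qseq or hi - lo < len(qseq):
            return None
        best: tuple[int, int, int] | None = None
        start = lo
        while True:
            pos = target.find(qseq, start, hi)
            if pos < 0:
                break
            score = (target[pos - 2 : pos] == "AG") + (
                target[pos + len(qseq) : pos + len(qseq) + 2] == "GT")
            key = (-score, abs(pos - near), pos)
            if best is None or key < best:
                best = key
            start = pos + 1
        return None if best is None else best[2]

    inserts: list[list[int]] = []
    for left, right in zip(blocks, blocks[1:]):
        qgap_lo, qgap_hi = left[3], right[2]
        if qgap_hi <= qgap_lo:
            continue
        qseq = query[qgap_lo:qgap_hi]
        pos = find(qseq, left[1] + 2, right[0] - 2, (left[1] + right[0]) // 2)
        if pos is not None:
            inserts.append([pos, pos + len(qseq), qgap_lo, qgap_hi])
    head = blocks[0]
    if head[2] > 0:
        qseq = query[: head[2]]
        lo = max(0, head[0] - 60 * len(qseq) - 10_000)
        pos = find(qseq, lo, head[0] - 2, head[0])
        if pos is not None:
            inserts.append([pos, pos + len(qseq), 0, head[2]])
    tail = blocks[-1]
    if tail[3] < len(query):
        qseq = query[tail[3] :]
        hi = min(len(target), tail[1] + 60 * len(qseq) + 10_000)
        pos = find(qseq, tail[1] + 2, hi, tail[1])
        if pos is not None:
            inserts.append([pos, pos + len(qseq), tail[3], len(query)])
    blocks.extend(inserts)
    blocks.sort()


def _shift_gtag(target: str, blocks: list[list[int]]) -> None:
    """Shift ambiguous intron junctions so introns start GT and end AG,
    provided the spliced sequence is unchanged."""
    for i in range(len(blocks) - 1):
        donor, acceptor = blocks[i][1], blocks[i + 1][0]
        if target[donor : donor + 2] == "GT" and target[acceptor - 2 : acceptor] == "AG":
            continue
        for d in sorted(range(-MAX_JUNCTION_SHIFT, MAX_JUNCTION_SHIFT + 1), key=abs):
            nd, na = donor + d, acceptor + d
            if nd <= blocks[i][0] or na >= blocks[i + 1][1] or na - nd < MIN_INTRON:
                continue
            if target[nd : nd + 2] != "GT" or target[na - 2 : na] != "AG":
                continue
            # the moved bases must be identical for the splice to be equivalent
            if d > 0 and target[donor:nd] != target[acceptor:na]:
                continue
            if d < 0 and target[nd:donor] != target[na:acceptor]:
                continue
            blocks[i][1], blocks[i + 1][0] = nd, na
            break


def _edlib_counts(query: str, target: str) -> tuple[int, int, int, int]:
    """(matches, mismatches, insertions_bp, deletions_bp) of a global alignment."""
    if not query or not target:
        return 0, 0, len(query), len(target)
    res = edlib.align(query, target, mode="NW", task="path")
    m = x = ins = dele = 0
    import re

    for n, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        n = int(n)
        if op == "=":
            m += n
        elif op == "X":
            x += n
        elif op == "I":
            ins += n
        elif op == "D":
            dele += n
    return m, x, ins, dele


def spliced_align(
    query: str,
    segment_seq: str,
    strand_hint: str = "+",
    k: int = SEED_K,
) -> Optional[SplicedAlignment]:
    """Align a CDS/cDNA onto a genomic segment, jumping introns.

    Returns the best spliced alignment on the hinted sense strand, or None
    when no seed chain is found.  Exon blocks are reported in ascending
    forward-strand coordinates of ``segment_seq``.
    """
    query = query.upper()
    target_fwd = segment_seq.upper()
    target = (
        str(Seq(target_fwd).reverse_complement()) if strand_hint == "-" else target_fwd
    )
    anchors = _mem_anchors(query, target, k)
    if not anchors:
        return None
    chain = _chain(anchors)
    if not chain:
        return None

    # group chained anchors into exons (target gaps >= MIN_INTRON are
    # introns); blocks are [t_start, t_end, q_start, q_end]
    blocks: list[list[int]] = [[chain[0][1], chain[0][1] + chain[0][2],
                                chain[0][0], chain[0][0] + chain[0][2]]]
    for (q, t, l), (pq, pt, pl) in zip(chain[1:], chain):
        qgap = q - (pq + pl)
        tgap = t - (pt + pl)
        if tgap - qgap >= MIN_INTRON:
            blocks.append([t, t + l, q, q + l])
        else:
            blocks[-1][1] = t + l
            blocks[-1][3] = q + l
    _rescue_micro_exons(query, target, blocks)
    _shift_gtag(target, blocks)

    q_start = blocks[0][2]
    q_end = blocks[-1][3]
    spliced = "".join(target[b[0] : b[1]] for b in blocks)
    m, x, ins, dele = _edlib_counts(query[q_start:q_end], spliced)
    if strand_hint == "-":
        L = len(target)
        fwd_blocks = sorted((L - b[1], L - b[0]) for b in blocks)
    else:
        fwd_blocks = [(b[0], b[1]) for b in blocks]
    return SplicedAlignment(
        exon_blocks=fwd_blocks,
        query_start=q_start,
        query_end=q_end,
        query_length=len(query),
        matches=m,
        mismatches=x,
        insertions_bp=ins,
        deletions_bp=dele,
        strand=strand_hint,
        spliced_seq=spliced,
    )


def orf_status(aln: Optional[SplicedAlignment],
               min_query_coverage: float = DEFAULT_MIN_QUERY_COVERAGE) -> str:
    """Classify the spliced sequence of an alignment as an open reading frame."""
    if aln is None:
        return "no_alignment"
    if aln.query_coverage < min_query_coverage:
        return "partial"
    seq = aln.spliced_seq
    if len(seq) % 3:
        return "not_multiple_of_3"
    if not seq.startswith("ATG") or seq[-3:] not in STOP_CODONS:
        return "partial"
    internal = {seq[i : i + 3] for i in range(0, len(seq) - 3, 3)}
    if internal & STOP_CODONS:
        return "premature_stop"
    return "intact"


# ---------------------------------------------------------------------------
# cluster checking


@dataclass
class LiftoverResult:
    cluster_id: str
    target_assembly: str
    segment: tuple[str, int, int, str]
    exon_blocks: list[tuple[int, int]]  # chromosome coordinates, ascending
    matches: int
    mismatches: int
    insertions_bp: int
    deletions_bp: int
    query_coverage: float
    orf_status: str
    verdict: str
    query_id: str = ""
    source_gene: str = ""
    strand: str = "+"


def _align_consensus_to_segment(
    consensus: list[SequenceRecord],
    asm: Assembly,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    pad: int,
    min_query_coverage: float,
) -> tuple[Optional[SplicedAlignment], Optional[SequenceRecord], int]:
    """Best consensus CDS alignment on a padded segment; returns (aln, record, pad_offset)."""
    lo = max(0, start - pad)
    hi = min(len(asm.chromosomes[chrom]), end + pad)
    seg_seq = asm.chromosomes[chrom][lo:hi]
    best: tuple[float, int, Optional[SplicedAlignment], Optional[SequenceRecord]] = (
        -1.0, 1 << 30, None, None,
    )
    for rec in sorted(consensus, key=lambda r: r.seq_id):
        aln = spliced_align(rec.sequence, seg_seq, strand_hint=strand)
        if aln is None:
            continue
        keyed = (aln.query_coverage, -(aln.mismatches + aln.insertions_bp + aln.deletions_bp))
        cur = (best[0], -best[1])
        if keyed > cur:
            best = (aln.query_coverage, aln.mismatches + aln.insertions_bp + aln.deletions_bp, aln, rec)
    return best[2], best[3], lo


def _result_from_alignment(
    cluster: PangeneCluster,
    asm: Assembly,
    chrom: str,
    strand: str,
    aln: Optional[SplicedAlignment],
    rec: Optional[SequenceRecord],
    offset: int,
    segment: tuple[str, int, int, str],
    confirm_verdict: str,
    min_query_coverage: float,
) -> LiftoverResult:
    status = orf_status(aln, min_query_coverage)
    if aln is None:
        return LiftoverResult(
            cluster.cluster_id, asm.assembly_id, segment, [], 0, 0, 0, 0,
            0.0, status, "rejected",
        )
    verdict = confirm_verdict if status == "intact" else "rejected"
    return LiftoverResult(
        cluster_id=cluster.cluster_id,
        target_assembly=asm.assembly_id,
        segment=segment,
        exon_blocks=[(offset + s, offset + e) for s, e in aln.exon_blocks],
        matches=aln.matches,
        mismatches=aln.mismatches,
        insertions_bp=aln.insertions_bp,
        deletions_bp=aln.deletions_bp,
        query_coverage=aln.query_coverage,
        orf_status=status,
        verdict=verdict,
        query_id=rec.seq_id if rec else "",
        source_gene=rec.gene_id if rec else "",
        strand=strand,
    )


def check_cluster(
    cluster: PangeneCluster,
    assemblies: list[Assembly],
    mode: str = "missing",
    pad: int = DEFAULT_FLANK_PAD,
    min_query_coverage: float = DEFAULT_MIN_QUERY_COVERAGE,
    outlier_frac: float = DEFAULT_OUTLIER_FRACTION,
    partner: Optional[PangeneCluster] = None,
) -> list[LiftoverResult]:
    """Lift the cluster's consensus CDS onto candidate loci and classify.

    missing mode: align against each gDNA segment member; the absence is
    rejected as a PAV (verdict ``missing_gene_confirmed``) only for an
    intact ORF covering the whole query.  split mode: align across the span
    of multi-member assemblies (``split_fix``).  merged mode: align this
    cluster's and ``partner``'s consensus inside a long member's locus;
    ``merged_fix`` requires both to align disjointly with intact ORFs.
    """
    if mode not in ("missing", "split", "merged", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    asm_by_id = {a.assembly_id: a for a in assemblies}
    cons = consensus_isoforms(cluster, outlier_frac).consensus_isoforms
    results: list[LiftoverResult] = []

    if mode in ("missing", "all"):
        for asm_id in sorted(cluster.gdna_members):
            if cluster.members.get(asm_id):
                continue  # assembly already has a gene member
            asm = asm_by_id[asm_id]
            for seg in cluster.gdna_members[asm_id]:
                donors = [r for r in cons if r.assembly_id != asm_id]
                aln, rec, off = _align_consensus_to_segment(
                    donors, asm, seg.chromosome, seg.start, seg.end,
                    seg.strand, pad, min_query_coverage,
                )
                results.append(
                    _result_from_alignment(
                        cluster, asm, seg.chromosome, seg.strand, aln, rec, off,
                        (seg.chromosome, seg.start, seg.end, seg.strand),
                        "missing_gene_confirmed", min_query_coverage,
                    )
                )
        if not cluster.gdna_members and mode == "missing":
            logger.info("cluster %s: no gdna segments to check", cluster.cluster_id)

    if mode in ("split", "all"):
        for asm_id, gids in sorted(cluster.members.items()):
            if len(gids) < 2:
                continue
            asm = asm_by_id[asm_id]
            genes = [asm.get_gene(g) for g in gids]
            chrom = genes[0].chromosome
            if any(g.chromosome != chrom for g in genes):
                continue
            lo = min(g.start for g in genes)
            hi = max(g.end for g in genes)
            strand = genes[0].strand
            donors = [r for r in cons if r.assembly_id != asm_id]
            aln, rec, off = _align_consensus_to_segment(
                donors, asm, chrom, lo, hi, strand, pad, min_query_coverage,
            )
            results.append(
                _result_from_alignment(
                    cluster, asm, chrom, strand, aln, rec, off,
                    (chrom, lo, hi, strand), "split_fix", min_query_coverage,
                )
            )

    if mode in ("merged", "all") and partner is not None:
        cons_b = consensus_isoforms(partner, outlier_frac).consensus_isoforms
        mode_a = consensus_isoforms(cluster, outlier_frac).mode_length
        mode_b = consensus_isoforms(partner, outlier_frac).mode_length
        for asm_id, gids in sorted(cluster.members.items()):
            asm = asm_by_id[asm_id]
            for gid in gids:
                g = asm.get_gene(gid)
                host_cds = max((t.cds_length for t in g.transcripts), default=0)
                if host_cds < 0.8 * (mode_a + mode_b):
                    continue  # not long enough to host both models
                sub: list[LiftoverResult] = []
                for cset, owner in ((cons, cluster), (cons_b, partner)):
                    donors = [r for r in cset if r.gene_id != gid]
                    aln, rec, off = _align_consensus_to_segment(
                        donors, asm, g.chromosome, g.start, g.end, g.strand,
                        pad, min_query_coverage,
                    )
                    sub.append(
                        _result_from_alignment(
                            owner, asm, g.chromosome, g.strand, aln, rec, off,
                            (g.chromosome, g.start, g.end, g.strand),
                            "merged_fix", min_query_coverage,
                        )
                    )
                ok = all(r.verdict == "merged_fix" for r in sub) and _disjoint(
                    sub[0].exon_blocks, sub[1].exon_blocks
                )
                if not ok:
                    for r in sub:
                        r.verdict = "rejected"
                results.extend(sub)
    if not results:
        logger.info("cluster %s: no %s-mode candidates", cluster.cluster_id, mode)
    return results


def _disjoint(blocks_a: list[tuple[int, int]], blocks_b: list[tuple[int, int]]) -> bool:
    for s1, e1 in blocks_a:
        for s2, e2 in blocks_b:
            if max(s1, s2) < min(e1, e2):
                return False
    return True


# ---------------------------------------------------------------------------
# patch GFF


def emit_patch_gff(results: list[LiftoverResult], path: str) -> int:
    """Write confirmed lift-over models as GFF3 (1-based inclusive).

    One gene/mRNA/exon/CDS block per confirmed result, sorted by
    (chromosome, start); rejected results are never written.  Returns the
    number of models written.
    """
    confirmed = [r for r in results if r.verdict in CONFIRM_VERDICTS and r.exon_blocks]
    confirmed.sort(key=lambda r: (r.segment[0], r.exon_blocks[0][0], r.cluster_id))
    # overlapping same-strand patches are legal but suspicious
    for r1, r2 in zip(confirmed, confirmed[1:]):
        if (
            r1.segment[0] == r2.segment[0]
            and r1.strand == r2.strand
            and r1.exon_blocks[-1][1] > r2.exon_blocks[0][0]
        ):
            logger.warning(
                "overlapping patch models %s and %s", r1.cluster_id, r2.cluster_id
            )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, r in enumerate(confirmed, 1):
            chrom = r.segment[0]
            gid = f"patch_{r.cluster_id}_{r.target_assembly}_{i}"
            start = r.exon_blocks[0][0] + 1
            end = r.exon_blocks[-1][1]
            attrs = (
                f"ID={gid};cluster_id={r.cluster_id};source_gene={r.source_gene};"
                f"source_sequence={r.query_id}"
            )
            fh.write(
                f"{chrom}\tpangenewga\tgene\t{start}\t{end}\t.\t{r.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{chrom}\tpangenewga\tmRNA\t{start}\t{end}\t.\t{r.strand}\t.\t"
                f"ID={gid}.t1;Parent={gid}\n"
            )
            # CDS phase bookkeeping follows transcript order (5'->3')
            blocks = list(r.exon_blocks)
            tx_order = blocks if r.strand == "+" else blocks[::-1]
            phases = []
            consumed = 0
            for s, e in tx_order:
                phases.append((3 - consumed % 3) % 3)
                consumed += e - s
            phase_by_block = {blk: ph for blk, ph in zip(tx_order, phases)}
            for s, e in blocks:
                fh.write(
                    f"{chrom}\tpangenewga\texon\t{s + 1}\t{e}\t.\t{r.strand}\t.\t"
                    f"Parent={gid}.t1\n"
                )
            for s, e in blocks:
                fh.write(
                    f"{chrom}\tpangenewga\tCDS\t{s + 1}\t{e}\t.\t{r.strand}\t"
                    f"{phase_by_block[(s, e)]}\tParent={gid}.t1\n"
                )
    return len(confirmed)
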