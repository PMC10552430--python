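"""Synthetic families of annotated assemblies with exact ground-truth PAF.

An ancestor genome with multi-exon protein-coding genes is mutated into n
derived assemblies: seeded SNPs and small intergenic indels emulate
divergence (pairwise ANI is roughly ``100(1 - 2 snp_rate)``), and planted
structural events emulate the phenomena a pangene protocol must handle —
partial gene deletions (PAV), inversions, split annotations, hidden
(present-but-unannotated) genes and tandem duplications.  Pairwise PAF
alignments are derived from the tracked coordinate maps rather than by
running an aligner, so projection tests are exact.

Events never overlap each other, and event-target gene bodies are excluded
from point mutation in *every* assembly so that event outcomes (e.g. exact
lift-over recovery of a hidden gene) are unambiguous.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from Bio.Seq import Seq

from .wga import WgaAlignment

__all__ = ["SimConfig", "GroundTruth", "SimResult", "simulate", "verify_against_truth"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: maximum run of single-side unmapped bases bridged as I/D ops inside one
#: PAF record; longer gaps split the alignment, as a real aligner would
MAX_BRIDGE = 50

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimConfig:
    seed: int = 0
    n_assemblies: int = 4
    n_chromosomes: int = 1
    n_genes: int = 50
    mean_gene_len: int = 1200
    mean_intergenic_len: int = 800
    exons_per_gene: tuple[int, int] = (1, 4)
    snp_rate: float = 0.015
    indel_rate: float = 0.0005
    n_deletions: int = 5
    n_inversions: int = 1
    n_split_annotations: int = 1
    n_hidden_genes: int = 1
    n_tandem_duplications: int = 1

    def validate(self) -> None:
        if not 0 <= self.snp_rate <= 1 or not 0 <= self.indel_rate <= 1:
            raise ValueError("rates must be in [0,1]")
        for name in ("n_deletions", "n_inversions", "n_split_annotations",
                     "n_hidden_genes", "n_tandem_duplications"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        needed = (self.n_deletions + 2 * self.n_inversions
                  + self.n_split_annotations + self.n_hidden_genes
                  + self.n_tandem_duplications)
        if needed > self.n_genes // 2:
            raise ValueError("too many events for the number of genes")


@dataclass
class _AncGene:
    anc_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]  # genomic, ascending, == CDS
    role: str = "normal"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GroundTruth:
    """Planted truth: the ortholog partition, event log and expectations."""

    assemblies: list[str]
    anc_genes: list[str]
    partition: dict[str, list[str]]  # anc gene -> ["asm:gene_id", ...]
    events: list[dict]
    expected_occupancy: dict[str, int]
    unperturbed: list[str]
    inverted_genes: dict[str, list[str]]  # assembly -> gene ids inside inversions
    split_genes: dict[str, str]  # anc gene -> assembly with split annotation
    tandem_genes: dict[str, str]
    hidden_genes: dict[str, str]
    deleted_genes: dict[str, str]
    hidden_exons: dict[str, list[tuple[int, int]]]  # anc gene -> derived exon coords
    hidden_chrom: dict[str, str] = field(default_factory=dict)
    hidden_strand: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)

    @staticmethod
    def anc_of(gene_id: str) -> str:
        """Recover the ancestral gene id from a derived gene id."""
        gid = gene_id
        if gid.endswith("_td"):
            gid = gid[:-3]
        if gid.endswith(".1") or gid.endswith(".2"):
            gid = gid[:-2]
        return gid.rsplit("_", 1)[0]


@dataclass
class _Derived:
    """One derived assembly: sequences, coordinate maps, annotation."""

    assembly_id: str
    seqs: dict[str, str]
    anc2der: dict[str, np.ndarray]
    orient: dict[str, np.ndarray]
    # (chrom, anc gene interval, derived copy start) per tandem duplication
    tandem_copies: list[tuple[str, int, int, int]] = field(default_factory=list)
    gff_lines: list[str] = field(default_factory=list)


@dataclass
class SimResult:
    config: SimConfig
    outdir: str
    fasta_paths: dict[str, str]
    gff_paths: dict[str, str]
    paf_paths: dict[tuple[str, str], str]
    truth: GroundTruth
    alignments: dict[tuple[str, str], list[WgaAlignment]]


# ---------------------------------------------------------------------------
# ancestor construction


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + non-stop codons + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _build_gene(rng: np.random.Generator, role: str,
                exon_range: tuple[int, int], mean_len: int):
    """Return (genomic sequence, exons relative to gene start, strand)."""
    if role == "deletion":
        # 5'-light structure: the last exon carries well over half of the
        # gene body so a candidate segment survives the planted deletion
        exon_lens = [90, 90, 90, 900]
        strand = "+"
    else:
        lo, hi = exon_range
        n_exons = int(rng.integers(lo, hi + 1))
        if role == "split":
            n_exons = max(n_exons, 2)
        n_codons = int(rng.integers(60, max(61, mean_len // 4)))
        cds_len = 3 * n_codons
        cuts = sorted(rng.choice(np.arange(30, cds_len - 30), size=n_exons - 1,
                                 replace=False)) if n_exons > 1 else []
        bounds = [0] + [int(c) for c in cuts] + [cds_len]
        exon_lens = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
        strand = "+" if role in ("deletion",) else ("+" if rng.random() < 0.5 else "-")
    cds = _random_cds(rng, sum(exon_lens) // 3)
    parts: list[str] = []
    exons_tx: list[tuple[int, int]] = []  # transcript-orientation gene-local coords
    off = 0
    pos = 0
    for i, L in enumerate(exon_lens):
        parts.append(cds[off : off + L])
        exons_tx.append((pos, pos + L))
        pos += L
        off += L
        if i < len(exon_lens) - 1:
            intron = "GT" + _random_seq(rng, int(rng.integers(56, 146))) + "AG"
            parts.append(intron)
            pos += len(intron)
    tx_seq = "".join(parts)
    if strand == "+":
        return tx_seq, exons_tx, strand
    gseq = str(Seq(tx_seq).reverse_complement())
    glen = len(gseq)
    exons = sorted((glen - e, glen - s) for s, e in exons_tx)
    return gseq, exons, strand


def _assign_roles(rng: np.random.Generator, cfg: SimConfig,
                  per_chrom: list[int]) -> list[str]:
    """Role per gene slot (flat list over chromosomes); inversions take
    adjacent slot pairs within one chromosome."""
    total = sum(per_chrom)
    roles = ["normal"] * total
    chrom_of = []
    for ci, n in enumerate(per_chrom):
        chrom_of += [ci] * n
    free = set(range(total))

    def take(idx: int, role: str) -> None:
        roles[idx] = role
        free.discard(idx)

    for _ in range(cfg.n_inversions):
        candidates = [i for i in sorted(free)
                      if i + 1 in free and chrom_of[i] == chrom_of[i + 1]]
        if not candidates:
            raise ValueError("cannot place inversion: no free adjacent gene pair")
        i = int(rng.choice(candidates))
        take(i, "inversion")
        take(i + 1, "inversion")
    for role, count in (("deletion", cfg.n_deletions),
                        ("split", cfg.n_split_annotations),
                        ("hidden", cfg.n_hidden_genes),
                        ("tandem", cfg.n_tandem_duplications)):
        for _ in range(count):
            if not free:
                raise ValueError("not enough genes for requested events")
            i = int(rng.choice(sorted(free)))
            take(i, role)
    return roles


def _build_ancestor(rng: np.random.Generator, cfg: SimConfig):
    per_chrom = [cfg.n_genes // cfg.n_chromosomes] * cfg.n_chromosomes
    per_chrom[0] += cfg.n_genes - sum(per_chrom)
    roles = _assign_roles(rng, cfg, per_chrom)
    chroms: dict[str, str] = {}
    genes: list[_AncGene] = []
    gi = 0
    for ci, n in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        parts: list[str] = []
        pos = 0
        for _ in range(n):
            spacer = max(250, int(rng.normal(cfg.mean_intergenic_len,
                                             cfg.mean_intergenic_len / 4)))
            parts.append(_random_seq(rng, spacer))
            pos += spacer
            gseq, exons_rel, strand = _build_gene(
                rng, roles[gi], cfg.exons_per_gene, cfg.mean_gene_len)
            genes.append(_AncGene(
                anc_id=f"g{gi:04d}", chrom=chrom, start=pos, end=pos + len(gseq),
                strand=strand,
                exons=[(pos + s, pos + e) for s, e in exons_rel],
                role=roles[gi],
            ))
            parts.append(gseq)
            pos += len(gseq)
            gi += 1
        parts.append(_random_seq(rng, max(250, int(rng.normal(
            cfg.mean_intergenic_len, cfg.mean_intergenic_len / 4)))))
        chroms[chrom] = "".join(parts)
    return chroms, genes


# ---------------------------------------------------------------------------
# derivation


def _protected_masks(chroms: dict[str, str], genes: list[_AncGene],
                     inversions: list[tuple[str, int, int]]):
    """(snp-protected, indel-eligible) boolean masks per chromosome."""
    snp_prot = {c: np.zeros(len(s), bool) for c, s in chroms.items()}
    genic = {c: np.zeros(len(s), bool) for c, s in chroms.items()}
    for g in genes:
        genic[g.chrom][max(0, g.start - 50) : g.end + 50] = True
        if g.role != "normal":
            snp_prot[g.chrom][max(0, g.start - 50) : g.end + 50] = True
        # splice-site dinucleotides and CDS termini stay intact everywhere
        snp_prot[g.chrom][g.exons[0][0] : g.exons[0][0] + 3] = True
        snp_prot[g.chrom][g.exons[-1][1] - 3 : g.exons[-1][1]] = True
        for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
            snp_prot[g.chrom][e1 : e1 + 2] = True
            snp_prot[g.chrom][s2 - 2 : s2] = True
    for chrom, s, e in inversions:
        snp_prot[chrom][max(0, s - 20) : e + 20] = True
        genic[chrom][max(0, s - 20) : e + 20] = True
    indel_ok = {c: ~genic[c] for c in chroms}
    return snp_prot, indel_ok


def _derive_assembly(
    rng: np.random.Generator,
    cfg: SimConfig,
    asm_id: str,
    chroms: dict[str, str],
    genes: list[_AncGene],
    snp_prot: dict[str, np.ndarray],
    indel_ok: dict[str, np.ndarray],
    events: list[dict],
) -> _Derived:
    """Apply SNPs, intergenic indels and this assembly's structural events."""
    my_events = [ev for ev in events if ev["assembly"] == asm_id]
    deletions: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    inversions: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    tandems: dict[str, list[tuple[int, int, int]]] = {c: [] for c in chroms}
    for ev in my_events:
        if ev["type"] == "deletion":
            deletions[ev["chrom"]].append((ev["start"], ev["end"]))
        elif ev["type"] == "inversion":
            inversions[ev["chrom"]].append((ev["start"], ev["end"]))
        elif ev["type"] == "tandem":
            tandems[ev["chrom"]].append(
                (ev["gene_start"], ev["gene_end"], ev["insert_at"]))

    der = _Derived(asm_id, {}, {}, {})
    bases = np.array(list("ACGT"))
    for chrom, anc_seq in chroms.items():
        L = len(anc_seq)
        seq = np.array(list(anc_seq))
        # SNPs
        mask = (rng.random(L) < cfg.snp_rate) & ~snp_prot[chrom]
        idx = np.flatnonzero(mask)
        for p in idx:
            choices = [b for b in "ACGT" if b != seq[p]]
            seq[p] = choices[rng.integers(0, 3)]
        # intergenic indels: position -> +seq (insert before) or -n (delete n)
        ins_at: dict[int, str] = {}
        del_iv: list[tuple[int, int]] = list(deletions[chrom])
        cand = np.flatnonzero((rng.random(L) < cfg.indel_rate) & indel_ok[chrom])
        for p in cand:
            n = int(rng.integers(1, 11))
            if rng.random() < 0.5:
                ins_at[int(p)] = _random_seq(rng, n)
            elif indel_ok[chrom][p : p + n].all():
                del_iv.append((int(p), int(p) + n))
        for gs, ge, at in tandems[chrom]:
            # copy of the (protected, hence unmutated) gene region
            ins_at[at] = anc_seq[gs:ge]
        del_iv.sort()
        # merge/drop overlapping deletion intervals (events never overlap;
        # random indel deletions might)
        merged: list[tuple[int, int]] = []
        for s, e in del_iv:
            if merged and s < merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        deleted = np.zeros(L, bool)
        for s, e in merged:
            deleted[s:e] = True

        inv_sorted = sorted(inversions[chrom])
        bounds = [0]
        for s, e in inv_sorted:
            bounds += [s, e]
        bounds.append(L)
        out: list[str] = []
        a2d = np.full(L, -1, dtype=np.int64)
        orient = np.zeros(L, dtype=np.int8)
        cursor = 0
        copy_starts: dict[int, int] = {}
        for bi in range(len(bounds) - 1):
            s, e = bounds[bi], bounds[bi + 1]
            if s >= e:
                continue
            inverted = (s, e) in inv_sorted
            if inverted:
                segment = "".join(seq[s:e])
                out.append(segment.translate(_COMPLEMENT)[::-1])
                for p in range(s, e):
                    a2d[p] = cursor + (e - 1 - p)
                orient[s:e] = -1
                cursor += e - s
                continue
            for p in range(s, e):
                if p in ins_at:
                    ins = ins_at[p]
                    copy_starts[p] = cursor
                    out.append(ins)
                    cursor += len(ins)
                if deleted[p]:
                    continue
                out.append(seq[p])
                a2d[p] = cursor
                orient[p] = 1
                cursor += 1
        der.seqs[chrom] = "".join(out)
        der.anc2der[chrom] = a2d
        der.orient[chrom] = orient
        for gs, ge, at in tandems[chrom]:
            der.tandem_copies.append((chrom, gs, ge, copy_starts[at]))
    return der


# ---------------------------------------------------------------------------
# derived annotation (GFF3)


def _map_interval(a2d: np.ndarray, orient: np.ndarray, s: int, e: int):
    vals = a2d[s:e]
    vals = vals[vals >= 0]
    if len(vals) == 0:
        return None
    return int(vals.min()), int(vals.max()) + 1


def _phases(exon_lens: list[int]) -> list[int]:
    phases = []
    consumed = 0
    for L in exon_lens:
        phases.append((3 - consumed % 3) % 3)
        consumed += L
    return phases


def _gff_for_gene(chrom: str, gene_id: str, strand: str,
                  exons: list[tuple[int, int]], phase_offset: int = 0) -> list[str]:
    """GFF3 lines (1-based) for one single-transcript gene; exons ascending."""
    gs, ge = exons[0][0], exons[-1][1]
    lines = [
        f"{chrom}\tsim\tgene\t{gs + 1}\t{ge}\t.\t{strand}\t.\tID={gene_id}",
        f"{chrom}\tsim\tmRNA\t{gs + 1}\t{ge}\t.\t{strand}\t.\t"
        f"ID={gene_id}.m1;Parent={gene_id}",
    ]
    tx_order = exons if strand == "+" else exons[::-1]
    consumed = phase_offset
    phase_by_block = {}
    for s, e in tx_order:
        phase_by_block[(s, e)] = (3 - consumed % 3) % 3
        consumed += e - s
    for s, e in exons:
        lines.append(f"{chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                     f"Parent={gene_id}.m1")
    for s, e in exons:
        lines.append(f"{chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{strand}\t"
                     f"{phase_by_block[(s, e)]}\tParent={gene_id}.m1")
    return lines


def _annotate_derived(der: _Derived, genes: list[_AncGene],
                      events: list[dict], truth: GroundTruth) -> None:
    asm = der.assembly_id
    skip: dict[str, str] = {}  # anc_id -> reason
    split_here: set[str] = set()
    for ev in events:
        if ev["assembly"] != asm:
            continue
        if ev["type"] in ("deletion", "hidden"):
            skip[ev["gene"]] = ev["type"]
        elif ev["type"] == "split":
            split_here.add(ev["gene"])

    entries: list[tuple[str, int, list[str]]] = []
    for g in genes:
        a2d, orient = der.anc2der[g.chrom], der.orient[g.chrom]
        gene_id = f"{g.anc_id}_{asm}"
        if g.anc_id in skip:
            if skip[g.anc_id] == "hidden":
                # present but unannotated: remember the derived coordinates
                ex = [_map_interval(a2d, orient, s, e) for s, e in g.exons]
                ex = sorted(x for x in ex if x)
                truth.hidden_exons[g.anc_id] = ex
                truth.hidden_chrom[g.anc_id] = g.chrom
                # events never overlap, so a hidden gene keeps its orientation
                truth.hidden_strand[g.anc_id] = g.strand
            continue
        flipped = orient[g.start] == -1
        strand = ("-" if g.strand == "+" else "+") if flipped else g.strand
        exons = sorted(x for x in (_map_interval(a2d, orient, s, e)
                                   for s, e in g.exons) if x)
        if not exons:
            continue
        if g.anc_id in split_here:
            tx_exons = exons if strand == "+" else exons[::-1]
            k = (len(tx_exons) + 1) // 2
            part1, part2 = tx_exons[:k], tx_exons[k:]
            consumed = sum(e - s for s, e in part1)
            for suffix, part, off in ((".1", part1, 0), (".2", part2, consumed)):
                part_sorted = sorted(part)
                lines = _gff_for_gene(g.chrom, gene_id + suffix, strand,
                                      part_sorted, phase_offset=off)
                entries.append((g.chrom, part_sorted[0][0], lines))
                truth.partition.setdefault(g.anc_id, []).append(
                    f"{asm}:{gene_id}{suffix}")
        else:
            lines = _gff_for_gene(g.chrom, gene_id, strand, exons)
            entries.append((g.chrom, exons[0][0], lines))
            truth.partition.setdefault(g.anc_id, []).append(f"{asm}:{gene_id}")
        if g.role == "tandem":
            for chrom, gs, ge, c0 in der.tandem_copies:
                if chrom == g.chrom and gs == g.start:
                    copy_exons = [(c0 + s - g.start, c0 + e - g.start)
                                  for s, e in g.exons]
                    lines = _gff_for_gene(g.chrom, gene_id + "_td", g.strand,
                                          copy_exons)
                    entries.append((g.chrom, copy_exons[0][0], lines))
                    truth.partition.setdefault(g.anc_id, []).append(
                        f"{asm}:{gene_id}_td")
    entries.sort(key=lambda x: (x[0], x[1]))
    der.gff_lines = ["##gff-version 3"]
    for _, _, lines in entries:
        der.gff_lines.extend(lines)


# ---------------------------------------------------------------------------
# exact pairwise PAF from the coordinate maps


class _RecordBuilder:
    def __init__(self, chrom: str, qlen: int, tlen: int,
                 asm_t: str, asm_q: str):
        self.chrom, self.qlen, self.tlen = chrom, qlen, tlen
        self.asm_t, self.asm_q = asm_t, asm_q
        self.reset()

    def reset(self) -> None:
        self.ops: list[list] = []
        self.t0 = self.q_anchor = None
        self.last_a = self.last_b = None
        self.strand = "+"

    def open(self, a: int, b: int, strand: str) -> None:
        self.reset()
        self.t0 = a
        self.q_anchor = b
        self.last_a, self.last_b = a, b
        self.strand = strand

    def push(self, n: int, op: str) -> None:
        if n <= 0:
            return
        if self.ops and self.ops[-1][1] == op:
            self.ops[-1][0] += n
        else:
            self.ops.append([n, op])

    def column(self, a: int, b: int, match: bool) -> None:
        gap_t = a - self.last_a - 1
        gap_q = (b - self.last_b - 1) if self.strand == "+" else (self.last_b - b - 1)
        self.push(gap_t, "D")
        self.push(gap_q, "I")
        self.push(1, "=" if match else "X")
        self.last_a, self.last_b = a, b

    def finish(self) -> WgaAlignment | None:
        if self.t0 is None or not self.ops:
            return None
        # trim trailing indels
        while self.ops and self.ops[-1][1] in "ID":
            self.ops.pop()
        if not self.ops:
            return None
        cigar = "".join(f"{n}{op}" for n, op in self.ops)
        t_start, t_end = self.t0, self.last_a + 1
        if self.strand == "+":
            q_start, q_end = self.q_anchor, self.last_b + 1
        else:
            q_start, q_end = self.last_b, self.q_anchor + 1
        aln = WgaAlignment(
            query_name=self.chrom, query_len=self.qlen,
            query_start=q_start, query_end=q_end, strand=self.strand,
            target_name=self.chrom, target_len=self.tlen,
            target_start=t_start, target_end=t_end, cigar=cigar,
            source_algorithm="simulated",
            query_assembly=self.asm_q, target_assembly=self.asm_t,
        )
        aln.validate()
        return aln


def _compose_pair(derA: _Derived, derB: _Derived,
                  chroms: dict[str, str]) -> list[WgaAlignment]:
    """Exact alignments of derB (query) against derA (target)."""
    records: list[WgaAlignment] = []
    for chrom in sorted(chroms):
        aA, aB = derA.anc2der[chrom], derB.anc2der[chrom]
        oA, oB = derA.orient[chrom], derB.orient[chrom]
        sA, sB = derA.seqs[chrom], derB.seqs[chrom]
        L = len(chroms[chrom])
        builder = _RecordBuilder(chrom, len(sB), len(sA),
                                 derA.assembly_id, derB.assembly_id)

        # split into runs of constant (orientA, orientB)
        state = oA.astype(np.int16) * 4 + oB.astype(np.int16)
        change = np.flatnonzero(np.diff(state)) + 1
        bounds = [0] + change.tolist() + [L]
        open_rec = False
        pending_break = True  # cannot bridge before the first mapped block

        def close() -> None:
            nonlocal open_rec
            if open_rec:
                rec = builder.finish()
                if rec is not None and rec.aligned_columns >= 20:
                    records.append(rec)
            open_rec = False

        for s, e in zip(bounds, bounds[1:]):
            sa, sb = int(oA[s]), int(oB[s])
            if sa == 0 and sb == 0:
                continue  # absent from both: invisible to the alignment
            if sa == 0 or sb == 0:
                if not open_rec:
                    continue
                if e - s > MAX_BRIDGE:
                    close()
                    pending_break = True
                    continue
                # bridge: one-sided bases become I/D ops at the next column
                continue
            strand = "+" if sa == sb else "-"
            walk = range(s, e) if sa == 1 else range(e - 1, s - 1, -1)
            first_p = s if sa == 1 else e - 1
            if open_rec and builder.strand != strand:
                close()
                pending_break = True
            if open_rec:
                # orientation blocks with sa == -1 never merge with neighbours
                if sa == -1 or pending_break:
                    close()
            for p in walk:
                a, b = int(aA[p]), int(aB[p])
                if a < 0 or b < 0:  # interior deletion inside the run
                    continue
                ca = sA[a]
                cb = sB[b]
                if strand == "-":
                    cb = cb.translate(_COMPLEMENT)
                if not open_rec:
                    builder.open(a, b, strand)
                    builder.push(1, "=" if ca == cb else "X")
                    open_rec = True
                else:
                    if a - builder.last_a - 1 > MAX_BRIDGE or \
                       abs(b - builder.last_b) - 1 > MAX_BRIDGE:
                        close()
                        builder.open(a, b, strand)
                        builder.push(1, "=" if ca == cb else "X")
                        open_rec = True
                        continue
                    builder.column(a, b, ca == cb)
            if sa == -1:
                close()
            pending_break = False
        close()

        # tandem copies align the partner's gene interval onto the copy
        for holder, other, holder_is_target in ((derA, derB, True),
                                                (derB, derA, False)):
            for tchrom, gs, ge, c0 in holder.tandem_copies:
                if tchrom != chrom:
                    continue
                a2o = other.anc2der[tchrom]
                copy_seq = holder.seqs[tchrom]
                b = _RecordBuilder(chrom, len(sB), len(sA),
                                   derA.assembly_id, derB.assembly_id)
                opened = False
                for p in range(gs, ge):
                    o = int(a2o[p])
                    if o < 0:
                        continue
                    c = c0 + (p - gs)
                    if holder_is_target:
                        a_pos, b_pos = c, o
                        ca, cb = copy_seq[c], other.seqs[tchrom][o]
                    else:
                        a_pos, b_pos = o, c
                        ca, cb = other.seqs[tchrom][o], copy_seq[c]
                    if not opened:
                        b.open(a_pos, b_pos, "+")
                        b.push(1, "=" if ca == cb else "X")
                        opened = True
                    else:
                        b.column(a_pos, b_pos, ca == cb)
                rec = b.finish() if opened else None
                if rec is not None and rec.aligned_columns >= 20:
                    records.append(rec)
    return records


# ---------------------------------------------------------------------------
# events


def _plan_events(rng: np.random.Generator, cfg: SimConfig,
                 genes: list[_AncGene], asm_ids: list[str]) -> list[dict]:
    """Assign each planted event to a non-reference assembly."""
    others = asm_ids[1:] if len(asm_ids) > 1 else asm_ids
    events: list[dict] = []

    def pick_asm() -> str:
        return str(others[rng.integers(0, len(others))])

    inv_genes = [g for g in genes if g.role == "inversion"]
    for i in range(0, len(inv_genes), 2):
        g1, g2 = inv_genes[i], inv_genes[i + 1]
        events.append({
            "type": "inversion", "assembly": pick_asm(), "chrom": g1.chrom,
            "start": g1.start - 20, "end": g2.end + 20,
            "genes": [g1.anc_id, g2.anc_id],
        })
    for g in genes:
        if g.role == "deletion":
            # exons 1-3 plus introns removed; last exon intact
            events.append({
                "type": "deletion", "assembly": pick_asm(), "chrom": g.chrom,
                "gene": g.anc_id, "start": g.start, "end": g.exons[-1][0],
            })
        elif g.role == "hidden":
            events.append({"type": "hidden", "assembly": pick_asm(),
                           "chrom": g.chrom, "gene": g.anc_id})
        elif g.role == "split":
            events.append({"type": "split", "assembly": pick_asm(),
                           "chrom": g.chrom, "gene": g.anc_id})
        elif g.role == "tandem":
            events.append({
                "type": "tandem", "assembly": pick_asm(), "chrom": g.chrom,
                "gene": g.anc_id, "gene_start": g.start, "gene_end": g.end,
                "insert_at": g.end + 40,
            })
    return events


# ---------------------------------------------------------------------------
# top level


def simulate(config: SimConfig, outdir: str) -> SimResult:
    """Generate assemblies (FASTA+GFF3), exact pairwise PAF and ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    os.makedirs(outdir, exist_ok=True)
    chroms, genes = _build_ancestor(rng, config)
    asm_ids = [f"A{i + 1}" for i in range(config.n_assemblies)]
    events = _plan_events(rng, config, genes, asm_ids)
    inv_regions = [(ev["chrom"], ev["start"], ev["end"])
                   for ev in events if ev["type"] == "inversion"]
    snp_prot, indel_ok = _protected_masks(chroms, genes, inv_regions)

    n = len(asm_ids)
    event_gene_asm = {ev.get("gene"): ev["assembly"] for ev in events
                      if ev["type"] in ("deletion", "hidden", "split", "tandem")}
    truth = GroundTruth(
        assemblies=asm_ids,
        anc_genes=[g.anc_id for g in genes],
        partition={},
        events=events,
        expected_occupancy={
            g.anc_id: (n - 1 if g.role in ("deletion", "hidden") else n)
            for g in genes
        },
        unperturbed=[g.anc_id for g in genes if g.role == "normal"],
        inverted_genes={},
        split_genes={ev["gene"]: ev["assembly"] for ev in events
                     if ev["type"] == "split"},
        tandem_genes={ev["gene"]: ev["assembly"] for ev in events
                      if ev["type"] == "tandem"},
        hidden_genes={ev["gene"]: ev["assembly"] for ev in events
                      if ev["type"] == "hidden"},
        deleted_genes={ev["gene"]: ev["assembly"] for ev in events
                       if ev["type"] == "deletion"},
        hidden_exons={},
    )
    for ev in events:
        if ev["type"] == "inversion":
            truth.inverted_genes.setdefault(ev["assembly"], []).extend(
                f"{g}_{ev['assembly']}" for g in ev["genes"])

    derived: dict[str, _Derived] = {}
    for asm in asm_ids:
        der = _derive_assembly(rng, config, asm, chroms, genes,
                               snp_prot, indel_ok, events)
        _annotate_derived(der, genes, events, truth)
        derived[asm] = der

    fasta_paths, gff_paths = {}, {}
    for asm in asm_ids:
        fa = os.path.join(outdir, f"{asm}.fna")
        gff = os.path.join(outdir, f"{asm}.gff3")
        with open(fa, "w") as fh:
            for chrom in sorted(derived[asm].seqs):
                fh.write(f">{chrom}\n")
                seq = derived[asm].seqs[chrom]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        with open(gff, "w") as fh:
            fh.write("\n".join(derived[asm].gff_lines) + "\n")
        fasta_paths[asm], gff_paths[asm] = fa, gff

    paf_paths: dict[tuple[str, str], str] = {}
    alignments: dict[tuple[str, str], list[WgaAlignment]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = asm_ids[i], asm_ids[j]
            alns = _compose_pair(derived[a], derived[b], chroms)
            alignments[(a, b)] = alns
            path = os.path.join(outdir, f"{a}-{b}.paf")
            with open(path, "w") as fh:
                for aln in alns:
                    fh.write("\t".join([
                        aln.query_name, str(aln.query_len),
                        str(aln.query_start), str(aln.query_end), aln.strand,
                        aln.target_name, str(aln.target_len),
                        str(aln.target_start), str(aln.target_end),
                        str(aln.aligned_columns),
                        str(aln.aligned_columns), "60", f"cg:Z:{aln.cigar}",
                    ]) + "\n")
            paf_paths[(a, b)] = path

    truth.to_json(os.path.join(outdir, "truth.json"))
    return SimResult(config, outdir, fasta_paths, gff_paths, paf_paths,
                     truth, alignments)


# ---------------------------------------------------------------------------
# scoring pipeline output against the planted truth


def verify_against_truth(clusters, liftover_results, truth: GroundTruth) -> dict:
    """Score clustering / flags / lift-over verdicts against the planted truth.

    ``clusters`` are flagged PangeneCluster objects; ``liftover_results`` a
    list of LiftoverResult from missing-mode checks.
    """
    n = len(truth.assemblies)
    cluster_of: dict[str, object] = {}
    for cl in clusters:
        for asm, gids in cl.members.items():
            for gid in gids:
                cluster_of[f"{asm}:{gid}"] = cl

    def cluster_for_anc(anc: str):
        for key in truth.partition.get(anc, []):
            if key in cluster_of:
                return cluster_of[key]
        return None

    # exact partition on unperturbed genes
    exact = True
    for anc in truth.unperturbed:
        expected = set(truth.partition[anc])
        cl = cluster_for_anc(anc)
        if cl is None:
            exact = False
            continue
        got = {f"{asm}:{gid}" for asm, gids in cl.members.items() for gid in gids}
        if got != expected:
            exact = False

    # occupancy / PAV
    true_pav = {a for a, occ in truth.expected_occupancy.items() if occ < n}
    pred_pav = set()
    occupancy_ok = True
    for anc in truth.anc_genes:
        cl = cluster_for_anc(anc)
        occ = cl.occupancy if cl is not None else 0
        if occ < n:
            pred_pav.add(anc)
        if occ != truth.expected_occupancy[anc]:
            occupancy_ok = False
    tp = len(true_pav & pred_pav)
    pav_recall = tp / len(true_pav) if true_pav else 1.0
    pav_precision = tp / len(pred_pav) if pred_pav else 1.0

    inversion_ok = True
    for asm, gids in truth.inverted_genes.items():
        for gid in gids:
            cl = cluster_of.get(f"{asm}:{gid}")
            if cl is None or gid not in cl.inverted_members:
                inversion_ok = False

    split_ok = all(
        (cluster_for_anc(anc) is not None
         and cluster_for_anc(anc).split_count >= 1)
        for anc in truth.split_genes
    )
    tandem_ok = all(
        (cluster_for_anc(anc) is not None
         and cluster_for_anc(anc).tandem_count >= 1)
        for anc in truth.tandem_genes
    )

    by_cluster: dict[str, list] = {}
    for r in liftover_results:
        by_cluster.setdefault(r.cluster_id, []).append(r)
    cluster_ids_of_anc = {}
    for anc in truth.anc_genes:
        cl = cluster_for_anc(anc)
        if cl is not None:
            cluster_ids_of_anc[anc] = cl.cluster_id

    hidden_confirmed = 0
    hidden_exact_patch = 0
    for anc in truth.hidden_genes:
        results = by_cluster.get(cluster_ids_of_anc.get(anc, ""), [])
        good = [r for r in results if r.verdict == "missing_gene_confirmed"
                and r.mismatches == 0 and r.insertions_bp == 0
                and r.deletions_bp == 0]
        if good:
            hidden_confirmed += 1
            planted = [tuple(x) for x in truth.hidden_exons.get(anc, [])]
            if any(list(map(tuple, r.exon_blocks)) == planted for r in good):
                hidden_exact_patch += 1
    deletions_rejected = 0
    for anc in truth.deleted_genes:
        results = by_cluster.get(cluster_ids_of_anc.get(anc, ""), [])
        if results and all(r.verdict == "rejected" for r in results):
            deletions_rejected += 1

    return {
        "partition_exact": exact,
        "occupancy_exact": occupancy_ok,
        "pav_recall": pav_recall,
        "pav_precision": pav_precision,
        "inversion_flags_correct": inversion_ok,
        "split_flags_correct": split_ok,
        "tandem_flags_correct": tandem_ok,
        "hidden_genes_confirmed": hidden_confirmed,
        "hidden_genes_total": len(truth.hidden_genes),
        "hidden_patch_exact": hidden_exact_patch,
        "deletions_rejected": deletions_rejected,
        "deletions_total": len(truth.deleted_genes),
    }
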