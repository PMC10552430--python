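"""Greedy construction of pangene clusters from collinear pairs.

Pairs are merged in a deterministic order (descending overlap, then member
ids) subject to the same-assembly neighbor-distance constraint: any two
members of a cluster that come from the same assembly must lie on the same
chromosome with at most ``max_neighbors`` annotated genes between them.  A
merge that would break this rule for any assembly is refused and both
clusters stand.  Genes never joined to anything become singleton clusters,
so every gene belongs to exactly one cluster.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .annotation_io import Assembly, GeneModel, SequenceRecord, cut_gdna, wrap_fasta
from .collinearity import CollinearPair, Member

__all__ = [
    "PangeneCluster",
    "greedy_cluster",
    "name_clusters",
    "attach_sequences",
    "write_cluster_fastas",
    "flag_structure",
]

DEFAULT_MAX_NEIGHBORS = 5

#: tolerance on summed CDS length when deciding whether multiple same-assembly
#: members are fragments of one split model (fraction of the mode CDS length)
SPLIT_LENGTH_TOLERANCE = 0.2


@dataclass
class PangeneCluster:
    cluster_id: str
    members: dict[str, list[str]]  # assembly_id -> gene ids
    gdna_members: dict[str, list[Member]] = field(default_factory=dict)
    sequences: dict[str, list[SequenceRecord]] = field(default_factory=dict)
    inverted_members: set[str] = field(default_factory=set)
    split_count: int = 0
    tandem_count: int = 0
    missing_sequence_members: list[str] = field(default_factory=list)

    @property
    def occupancy(self) -> int:
        """Number of assemblies contributing >= 1 gene member (segments do not count)."""
        return sum(1 for v in self.members.values() if v)

    @property
    def inverted_count(self) -> int:
        return len(self.inverted_members)

    def gene_ids(self) -> list[str]:
        return sorted(gid for v in self.members.values() for gid in v)


class _ClusterBuilder:
    """Union-find over genes with the per-assembly distance constraint."""

    def __init__(self, genes: dict[str, GeneModel], max_neighbors: int):
        self.genes = genes
        self.max_neighbors = max_neighbors
        self.parent = {k: k for k in genes}
        # cluster key -> assembly -> (chromosome, min_rank, max_rank) or None (conflict-free cache)
        self.members: dict[str, list[str]] = {k: [k] for k in genes}

    def find(self, k: str) -> str:
        while self.parent[k] != k:
            self.parent[k] = self.parent[self.parent[k]]
            k = self.parent[k]
        return k

    def _violates(self, keys_a: list[str], keys_b: list[str]) -> bool:
        span: dict[str, tuple[str, int, int]] = {}
        for key in keys_a + keys_b:
            g = self.genes[key]
            cur = span.get(g.assembly_id)
            if cur is None:
                span[g.assembly_id] = (g.chromosome, g.order_rank, g.order_rank)
            else:
                chrom, lo, hi = cur
                if chrom != g.chromosome:
                    return True
                span[g.assembly_id] = (chrom, min(lo, g.order_rank), max(hi, g.order_rank))
        for chrom, lo, hi in span.values():
            if hi - lo - 1 > self.max_neighbors:
                return True
        return False

    def union(self, a: str, b: str) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return True
        if self._violates(self.members[ra], self.members[rb]):
            return False
        if len(self.members[ra]) < len(self.members[rb]):
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.members[ra].extend(self.members.pop(rb))
        return True


def _gene_key(assembly_id: str, gene_id: str) -> str:
    return f"{assembly_id}\t{gene_id}"


def _minority_orientation(
    member_keys: list[str], edges: list[tuple[str, str, int]]
) -> set[str]:
    """Two-color members by pair parity; the strictly smaller orientation
    group is reported as inverted (ties flag nothing)."""
    if not edges:
        return set()
    adj: dict[str, list[tuple[str, int]]] = {k: [] for k in member_keys}
    for a, b, par in edges:
        adj[a].append((b, par))
        adj[b].append((a, par))
    color: dict[str, int] = {}
    for start in member_keys:
        if start in color:
            continue
        color[start] = 0
        queue = [start]
        while queue:
            u = queue.pop()
            for v, par in adj[u]:
                want = color[u] ^ par
                if v not in color:
                    color[v] = want
                    queue.append(v)
                # conflicting parity evidence: first assignment wins
    ones = {k for k, c in color.items() if c == 1}
    zeros = {k for k, c in color.items() if c == 0}
    if len(ones) < len(zeros):
        return ones
    if len(zeros) < len(ones):
        return zeros
    return set()


def greedy_cluster(
    pairs: list[CollinearPair],
    assemblies: list[Assembly],
    max_neighbors: int = DEFAULT_MAX_NEIGHBORS,
) -> list[PangeneCluster]:
    """Merge collinear pairs into pangene clusters.

    Gene-gene pairs are processed in deterministic order (descending
    overlap_bp, then member ids); gene-gdna pairs are attached afterwards to
    the cluster of their gene member.  Raises KeyError for pairs naming
    unknown genes.
    """
    genes: dict[str, GeneModel] = {}
    for asm in assemblies:
        for g in asm.all_genes():
            genes[_gene_key(asm.assembly_id, g.gene_id)] = g

    def key_of(m: Member) -> str:
        k = _gene_key(m.assembly, m.id)
        if k not in genes:
            raise KeyError(f"pair references unknown gene {m.id!r} in {m.assembly!r}")
        return k

    builder = _ClusterBuilder(genes, max_neighbors)
    gene_pairs = [p for p in pairs if p.pair_type == "gene-gene"]
    gene_pairs.sort(
        key=lambda p: (-p.overlap_bp, p.member_a.assembly, p.member_a.id,
                       p.member_b.assembly, p.member_b.id)
    )
    # parity edges: inverted pairs put their members in opposite orientation
    # groups; within a cluster the minority group is flagged inverted
    parity_edges: list[tuple[str, str, int]] = []
    for p in gene_pairs:
        ka, kb = key_of(p.member_a), key_of(p.member_b)
        builder.union(ka, kb)
        parity_edges.append((ka, kb, 1 if p.inverted else 0))

    clusters: list[PangeneCluster] = []
    cluster_of_gene: dict[str, PangeneCluster] = {}
    asm_ids = [a.assembly_id for a in assemblies]
    root_of = {k: builder.find(k) for k in genes}
    edges_by_root: dict[str, list[tuple[str, str, int]]] = {}
    for ka, kb, par in parity_edges:
        if root_of[ka] == root_of[kb]:
            edges_by_root.setdefault(root_of[ka], []).append((ka, kb, par))
    for root in sorted(builder.members):
        member_keys = sorted(builder.members[root])
        inverted_keys = _minority_orientation(
            member_keys, edges_by_root.get(builder.find(root), [])
        )
        members: dict[str, list[str]] = {a: [] for a in asm_ids}
        inv: set[str] = set()
        for k in member_keys:
            asm, gid = k.split("\t")
            members[asm].append(gid)
            if k in inverted_keys:
                inv.add(gid)
        for asm in members:
            members[asm].sort(key=lambda gid: genes[_gene_key(asm, gid)].order_rank)
        cl = PangeneCluster("", members, inverted_members=inv)
        clusters.append(cl)
        for k in member_keys:
            cluster_of_gene[k] = cl

    # attach gene-gdna evidence to the gene member's cluster
    for p in pairs:
        if p.pair_type != "gene-gdna":
            continue
        gene_m = p.member_a if not p.member_a.id.startswith("segment:") else p.member_b
        seg_m = p.member_b if gene_m is p.member_a else p.member_a
        cl = cluster_of_gene[key_of(gene_m)]
        cl.gdna_members.setdefault(seg_m.assembly, [])
        if seg_m not in cl.gdna_members[seg_m.assembly]:
            cl.gdna_members[seg_m.assembly].append(seg_m)
    return clusters


def name_clusters(
    clusters: list[PangeneCluster], reference_assembly: Optional[str] = None
) -> list[PangeneCluster]:
    """Assign cluster ids from the reference-assembly member (or the
    lexicographically smallest member), de-duplicated with numeric suffixes."""
    taken: dict[str, int] = {}
    for cl in clusters:
        if reference_assembly and cl.members.get(reference_assembly):
            base = cl.members[reference_assembly][0]  # lowest order_rank
        else:
            base = min(cl.gene_ids(), default="cluster")
        n = taken.get(base, 0) + 1
        taken[base] = n
        cl.cluster_id = base if n == 1 else f"{base}_{n}"
    return clusters


def attach_sequences(
    clusters: list[PangeneCluster],
    records: Iterable[SequenceRecord],
    assemblies: Optional[list[Assembly]] = None,
) -> list[PangeneCluster]:
    """Attach every isoform sequence of every member to its cluster, and cut
    gDNA slices for segment members when assemblies are supplied."""
    by_gene: dict[tuple[str, str], list[SequenceRecord]] = {}
    for rec in records:
        by_gene.setdefault((rec.assembly_id, rec.gene_id), []).append(rec)
    asm_by_id = {a.assembly_id: a for a in assemblies or []}
    for cl in clusters:
        cl.sequences = {"cdna": [], "cds": [], "pep": [], "gdna": []}
        cl.missing_sequence_members = []
        for asm in sorted(cl.members):
            for gid in cl.members[asm]:
                recs = by_gene.get((asm, gid), [])
                if not recs:
                    cl.missing_sequence_members.append(f"{asm}:{gid}")
                for rec in sorted(recs, key=lambda r: (r.kind, r.seq_id)):
                    cl.sequences[rec.kind].append(rec)
        for asm in sorted(cl.gdna_members):
            for seg in cl.gdna_members[asm]:
                if asm in asm_by_id:
                    cl.sequences["gdna"].append(
                        cut_gdna(asm_by_id[asm],
                                 (seg.chromosome, seg.start, seg.end, seg.strand))
                    )
    return clusters


def write_cluster_fastas(clusters: list[PangeneCluster], outdir: str) -> None:
    """One FASTA per cluster per kind: <cluster_id>.<kind>.{fna,faa}."""
    os.makedirs(outdir, exist_ok=True)
    for cl in clusters:
        for kind, recs in cl.sequences.items():
            if not recs:
                continue
            ext = "faa" if kind == "pep" else "fna"
            path = os.path.join(outdir, f"{cl.cluster_id}.{kind}.{ext}")
            with open(path, "w") as fh:
                for rec in recs:
                    fh.write(f">{rec.seq_id}\n{wrap_fasta(rec.sequence)}")


def flag_structure(
    clusters: list[PangeneCluster],
    assemblies: list[Assembly],
    max_neighbors: int = DEFAULT_MAX_NEIGHBORS,
) -> list[PangeneCluster]:
    """Annotate clusters with split / tandem / inverted counts.

    The mode gene model is the most frequent representative CDS length
    across assemblies (ties -> longest).  An assembly contributing k > 1
    members whose *summed* CDS length is within ``SPLIT_LENGTH_TOLERANCE``
    of the mode contributes k-1 split models; multi-member assemblies not
    explained as splits contribute k-1 tandem copies.
    """
    cds_len: dict[tuple[str, str], int] = {}
    for asm in assemblies:
        for g in asm.all_genes():
            best = max((t.cds_length for t in g.transcripts), default=0)
            cds_len[(asm.assembly_id, g.gene_id)] = best

    for cl in clusters:
        lengths: list[int] = []
        for asm, gids in cl.members.items():
            for gid in gids:
                L = cds_len.get((asm, gid), 0)
                if L:
                    lengths.append(L)
        cl.split_count = 0
        cl.tandem_count = 0
        if not lengths:
            continue
        counts: dict[int, int] = {}
        for L in lengths:
            counts[L] = counts.get(L, 0) + 1
        mode = max(counts, key=lambda L: (counts[L], L))
        tol = SPLIT_LENGTH_TOLERANCE * mode
        for asm, gids in cl.members.items():
            k = len(gids)
            if k <= 1:
                continue
            total = sum(cds_len.get((asm, gid), 0) for gid in gids)
            if abs(total - mode) <= tol:
                cl.split_count += k - 1
            else:
                cl.tandem_count += k - 1
    return clusters
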