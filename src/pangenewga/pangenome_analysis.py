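"""Occupancy classification, pangene / POCS matrices and growth curves.

Occupancy is the number of genomes contributing at least one gene member to
a cluster (gDNA segment members never count).  Core clusters reach all n
genomes; soft-core clusters reach at least ceil(0.95 n); shell clusters sit
between singletons and soft-core; singletons occupy exactly one genome.
For reporting totals, soft-core counts include core clusters.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .annotation_io import Assembly
from .clustering import PangeneCluster

__all__ = [
    "classify_occupancy",
    "occupancy_counts",
    "build_pangene_matrix",
    "write_pangene_matrix",
    "pocs_matrix",
    "growth_curves",
]

DEFAULT_SOFTCORE_FRACTION = 0.95


def softcore_threshold(n_genomes: int, softcore_frac: float = DEFAULT_SOFTCORE_FRACTION) -> int:
    return math.ceil(softcore_frac * n_genomes)


def classify_occupancy(
    cluster: PangeneCluster,
    n_genomes: int,
    softcore_frac: float = DEFAULT_SOFTCORE_FRACTION,
) -> str:
    """Classify one cluster as core / softcore / shell / singleton."""
    occ = cluster.occupancy
    if occ > n_genomes:
        raise ValueError(
            f"cluster {cluster.cluster_id}: occupancy {occ} exceeds {n_genomes}"
        )
    if occ == n_genomes:
        return "core"
    if occ >= softcore_threshold(n_genomes, softcore_frac):
        return "softcore"
    if occ == 1:
        return "singleton"
    if occ == 0:
        raise ValueError(f"cluster {cluster.cluster_id}: zero occupancy")
    return "shell"


def occupancy_counts(
    clusters: list[PangeneCluster],
    n_genomes: int,
    softcore_frac: float = DEFAULT_SOFTCORE_FRACTION,
) -> dict[str, int]:
    """Counts per occupancy class, plus the inclusive soft-core total."""
    counts = {"core": 0, "softcore": 0, "shell": 0, "singleton": 0}
    for cl in clusters:
        counts[classify_occupancy(cl, n_genomes, softcore_frac)] += 1
    counts["softcore_total"] = counts["core"] + counts["softcore"]
    counts["total"] = len(clusters)
    return counts


def _reference_interval(cluster: PangeneCluster, assemblies: list[Assembly]):
    """(chromosome, start, end) of the naming member, if locatable."""
    for asm in assemblies:
        for gids in (cluster.members.get(asm.assembly_id, []),):
            for gid in gids:
                if gid == cluster.cluster_id or cluster.cluster_id.startswith(gid):
                    g = asm.get_gene(gid)
                    return g.chromosome, g.start, g.end
    return None


def build_pangene_matrix(
    clusters: list[PangeneCluster], assemblies: list[Assembly]
) -> pd.DataFrame:
    """BED-like pangene matrix: one row per cluster, one column per assembly.

    Cells hold comma-joined gene ids, a ``segment:`` descriptor, or '-'.
    Rows sort by the naming member's (chromosome, start); clusters without a
    locatable naming member go to an unsorted tail block.
    """
    asm_ids = [a.assembly_id for a in assemblies]
    rows = []
    for cl in clusters:
        loc = _reference_interval(cl, assemblies)
        row: dict[str, object] = {
            "chrom": loc[0] if loc else ".",
            "start": loc[1] if loc else -1,
            "end": loc[2] if loc else -1,
            "cluster_id": cl.cluster_id,
            "occupancy": cl.occupancy,
        }
        for asm in asm_ids:
            genes = cl.members.get(asm, [])
            segs = cl.gdna_members.get(asm, [])
            if genes:
                row[asm] = ",".join(genes)
            elif segs:
                row[asm] = ",".join(s.id for s in segs)
            else:
                row[asm] = "-"
        rows.append((loc is None, loc or ("~", 0, 0), row))
    rows.sort(key=lambda r: (r[0], r[1]))
    df = pd.DataFrame([r[2] for r in rows],
                      columns=["chrom", "start", "end", "cluster_id", "occupancy"] + asm_ids)
    return df


def write_pangene_matrix(df: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def pocs_matrix(
    clusters: list[PangeneCluster], assemblies: list[Assembly]
) -> pd.DataFrame:
    """Percentage of conserved sequences between every assembly pair.

    POCS(A,B) = 100 (g_A + g_B) / (T_A + T_B) where g_X counts genes of X in
    clusters containing both A and B, and T_X counts all clustered genes of
    X.  Symmetric with diagonal 100; assemblies with no genes are NaN.
    """
    asm_ids = [a.assembly_id for a in assemblies]
    totals = {a: 0 for a in asm_ids}
    for cl in clusters:
        for asm, gids in cl.members.items():
            totals[asm] += len(gids)
    mat = pd.DataFrame(np.nan, index=asm_ids, columns=asm_ids, dtype=float)
    for i, a in enumerate(asm_ids):
        for b in asm_ids[i:]:
            if totals[a] == 0 or totals[b] == 0:
                continue
            if a == b:
                mat.loc[a, b] = 100.0
                continue
            ga = gb = 0
            for cl in clusters:
                if cl.members.get(a) and cl.members.get(b):
                    ga += len(cl.members[a])
                    gb += len(cl.members[b])
            val = 100.0 * (ga + gb) / (totals[a] + totals[b])
            mat.loc[a, b] = val
            mat.loc[b, a] = val
    return mat


def growth_curves(
    clusters: list[PangeneCluster],
    assemblies: list[Assembly],
    n_perm: int = 10,
    seed: int = 0,
    softcore_frac: float = DEFAULT_SOFTCORE_FRACTION,
) -> pd.DataFrame:
    """Sampled pan / soft-core / core genome sizes versus number of genomes.

    For each seeded random permutation of the assemblies and each prefix
    length k, counts clusters with >= 1 member among the first k (pan), with
    members in all k (core) and in >= ceil(softcore_frac * k) (soft-core,
    inclusive of core).  Returns per-k means and standard deviations.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(assemblies) < 2:
        raise ValueError("need at least 2 assemblies")
    rng = np.random.default_rng(seed)
    asm_ids = [a.assembly_id for a in assemblies]
    presence = [
        frozenset(a for a, g in cl.members.items() if g) for cl in clusters
    ]
    n = len(asm_ids)
    pan = np.zeros((n_perm, n), dtype=int)
    core = np.zeros((n_perm, n), dtype=int)
    soft = np.zeros((n_perm, n), dtype=int)
    for p in range(n_perm):
        order = list(rng.permutation(asm_ids))
        for k in range(1, n + 1):
            prefix = set(order[:k])
            thr = softcore_threshold(k, softcore_frac)
            for pres in presence:
                hits = len(pres & prefix)
                if hits >= 1:
                    pan[p, k - 1] += 1
                if hits == k:
                    core[p, k - 1] += 1
                if hits >= thr:
                    soft[p, k - 1] += 1
    return pd.DataFrame(
        {
            "n_genomes": np.arange(1, n + 1),
            "pan_mean": pan.mean(axis=0),
            "pan_sd": pan.std(axis=0),
            "softcore_mean": soft.mean(axis=0),
            "softcore_sd": soft.std(axis=0),
            "core_mean": core.mean(axis=0),
            "core_sd": core.std(axis=0),
        }
    )
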