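"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results per base / per feature pair
with no shared code with the library, so the tests check the implementation
against an independent formulation of the same rules.
"""

from __future__ import annotations

import numpy as np
import pytest

from pangenewga.annotation_io import Assembly, GeneModel, Transcript
from pangenewga.wga import WgaAlignment


# ---------------------------------------------------------------------------
# oracles


def per_base_map(aln: WgaAlignment) -> dict[int, int]:
    """Brute-force per-base projection map query->target from the CIGAR."""
    import re

    t = aln.target_start
    if aln.strand == "+":
        q, step = aln.query_start, 1
    else:
        q, step = aln.query_end - 1, -1
    out: dict[int, int] = {}
    for n, op in re.findall(r"(\d+)([MIDX=])", aln.cigar):
        n = int(n)
        if op in "M=X":
            for _ in range(n):
                out[q] = t
                q += step
                t += 1
        elif op == "I":
            q += step * n
        elif op == "D":
            t += n
    return out


def brute_force_collinear(projected, genes, f=0.5):
    """O(n*m) scanner implementing 'overlap >= f of either AND same strand'."""
    pairs = set()
    for pg in projected:
        for g in genes:
            if g.chromosome != pg.target_chromosome:
                continue
            ov = min(g.end, pg.target_end) - max(g.start, pg.target_start)
            if ov <= 0:
                continue
            if pg.projected_strand != g.strand:
                continue
            if ov >= f * (g.end - g.start) or ov >= f * (pg.target_end - pg.target_start):
                pairs.add((g.gene_id, pg.gene.gene_id, ov))
    return pairs


def random_alignment(rng: np.random.Generator, max_len=10_000,
                     extended=True) -> WgaAlignment:
    """A random consistent alignment with ops from M/=/X/I/D, both strands."""
    n_ops = int(rng.integers(1, 20))
    ops = []
    aligned = False
    alpha = "=XMID" if extended else "MID"
    for _ in range(n_ops):
        op = alpha[int(rng.integers(0, len(alpha)))]
        L = int(rng.integers(1, max_len // 20 + 1))
        ops.append((L, op))
        if op in "M=X":
            aligned = True
    if not aligned:
        ops.append((int(rng.integers(1, 100)), "="))
    # no leading/trailing indels (PAF alignments are anchored on matches)
    while ops and ops[0][1] in "ID":
        ops.pop(0)
    while ops and ops[-1][1] in "ID":
        ops.pop()
    qspan = sum(n for n, op in ops if op in "M=XI")
    tspan = sum(n for n, op in ops if op in "M=XD")
    qs = int(rng.integers(0, 100))
    ts = int(rng.integers(0, 100))
    return WgaAlignment(
        query_name="q", query_len=qs + qspan + int(rng.integers(0, 100)),
        query_start=qs, query_end=qs + qspan,
        strand="+" if rng.random() < 0.5 else "-",
        target_name="t", target_len=ts + tspan + int(rng.integers(0, 100)),
        target_start=ts, target_end=ts + tspan,
        cigar="".join(f"{n}{op}" for n, op in ops),
    )


# ---------------------------------------------------------------------------
# tiny in-memory assemblies


def make_gene(gene_id, chrom, start, end, strand="+", exons=None, cds=None,
              tx_suffix=".t1"):
    exons = exons or [(start, end)]
    if cds is None:
        cds = [(s, e, 0) for s, e in exons]
    return GeneModel(
        gene_id, chrom, start, end, strand,
        [Transcript(gene_id + tx_suffix, exons, cds)],
    )


def make_assembly(assembly_id, chrom_seqs: dict[str, str], genes: list[GeneModel]):
    index: dict[str, list[GeneModel]] = {c: [] for c in chrom_seqs}
    for g in genes:
        index[g.chromosome].append(g)
    return Assembly(assembly_id, chrom_seqs, index)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_assembly(rng):
    """10 kb chromosome with 3 well-separated forward/reverse genes."""
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10_000)])
    genes = [
        make_gene("gA", "chr1", 1000, 1600, "+",
                  exons=[(1000, 1200), (1400, 1600)]),
        make_gene("gB", "chr1", 3000, 3900, "-"),
        make_gene("gC", "chr1", 6000, 6450, "+"),
    ]
    return make_assembly("T1", {"chr1": seq}, genes)


@pytest.fixture
def sim_bundle(tmp_path):
    """A small seeded simulation shared by integration-style tests."""
    from pangenewga.simulate import SimConfig, simulate

    return simulate(SimConfig(seed=11), str(tmp_path / "sim"))
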