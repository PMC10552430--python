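"""Serial pipeline: cut → align/import → collinear → cluster → matrices → check.

Every stage is deterministic for a fixed configuration and seed: inputs are
processed in sorted order, never filesystem order, so reruns are
byte-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional

from . import annotation_io, collinearity, clustering, liftover, pangenome_analysis, wga
from .annotation_io import Assembly
from .collinearity import CollinearPair, ProjectedGene
from .wga import WgaAlignment

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "call_pair_evidence"]


@dataclass
class RunConfig:
    assemblies: list[tuple[str, str, str]]  # (assembly_id, fasta, gff3)
    paf_paths: dict[tuple[str, str], str] = field(default_factory=dict)
    outdir: str = "pangenes_out"
    overlap_fraction: float = collinearity.DEFAULT_OVERLAP_FRACTION
    min_coverage: float = collinearity.DEFAULT_MIN_COVERAGE
    max_neighbors: int = clustering.DEFAULT_MAX_NEIGHBORS
    min_len: int = annotation_io.DEFAULT_MIN_LEN
    mask_geneless_bp: Optional[int] = None
    homologous_regex: Optional[str] = None
    softcore_fraction: float = pangenome_analysis.DEFAULT_SOFTCORE_FRACTION
    reference_assembly: Optional[str] = None
    liftover_occupancy_min: Optional[int] = None  # default n // 2
    liftover_min_query_coverage: float = liftover.DEFAULT_MIN_QUERY_COVERAGE
    seed: int = 0
    wga_algorithm: str = "simulated"
    growth_permutations: int = 10

    def validate(self) -> None:
        if len(self.assemblies) < 2:
            raise ValueError("need at least 2 assemblies for clustering")
        seen = set()
        for asm_id, fasta, gff in self.assemblies:
            if asm_id in seen:
                raise ValueError(f"duplicate assembly id {asm_id!r}")
            seen.add(asm_id)
            for path in (fasta, gff):
                if not os.path.exists(path):
                    raise ValueError(f"{asm_id}: missing input file {path}")
        for pair, path in self.paf_paths.items():
            if not os.path.exists(path):
                raise ValueError(f"pair {pair}: missing PAF {path}")


@dataclass
class PipelineResult:
    config: RunConfig
    assemblies: list[Assembly]
    pairs: list[CollinearPair]
    clusters: list
    occupancy: dict[str, int]
    pangene_matrix: object
    pocs: object
    ani: object
    growth: object
    liftover_results: list
    manifest: dict


def call_pair_evidence(
    target: Assembly,
    query: Assembly,
    alignments: list[WgaAlignment],
    overlap_fraction: float,
    min_coverage: float,
    wga_algorithm: str,
) -> list[CollinearPair]:
    """Collinear evidence for one aligned assembly pair, both directions.

    The pair is aligned once (``target`` as PAF target); query-side genes
    are projected forward through the alignment blocks and target-side genes
    backward through the same blocks with roles swapped.  Genes whose
    projection pairs with no gene become gene↔segment matches, unless they
    already found a gene-gene partner in that assembly.
    """
    segments = []
    for aln in alignments:
        segments.extend(wga.cigar_to_segments(aln))
    pairs: list[CollinearPair] = []
    for genes_asm, other_asm, segs in (
        (query, target, segments),
        (target, query, [s.swapped() for s in segments]),
    ):
        projected: list[ProjectedGene] = []
        for gene in genes_asm.all_genes():
            pg = collinearity.project_gene(
                gene, segs, min_coverage=min_coverage,
                target_assembly=other_asm.assembly_id,
            )
            if pg is not None:
                projected.append(pg)
        gene_pairs = collinearity.call_collinear_pairs(
            projected, other_asm, f=overlap_fraction, wga_algorithm=wga_algorithm,
        )
        matched = {p.member_b.id for p in gene_pairs}
        unpaired = [pg for pg in projected if pg.gene.gene_id not in matched]
        gdna = collinearity.call_gdna_matches(
            unpaired, other_asm, min_coverage=min_coverage,
            wga_algorithm=wga_algorithm,
        )
        pairs.extend(gene_pairs)
        pairs.extend(gdna)
    return pairs


def run_pipeline(config: RunConfig) -> PipelineResult:
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)

    # stage: load + cut
    assemblies = [
        annotation_io.load_assembly(fasta, gff, asm_id)
        for asm_id, fasta, gff in sorted(config.assemblies)
    ]
    asm_by_id = {a.assembly_id: a for a in assemblies}
    records = []
    for asm in assemblies:
        records.extend(annotation_io.cut_sequences(asm, min_len=config.min_len))
        if config.mask_geneless_bp is not None:
            masked = annotation_io.mask_geneless(asm, config.mask_geneless_bp)
            with open(os.path.join(config.outdir,
                                   f"{asm.assembly_id}.masked.fna"), "w") as fh:
                fh.write(masked)

    # stage: import alignments
    alignments: dict[tuple[str, str], list[WgaAlignment]] = {}
    for (a, b), path in sorted(config.paf_paths.items()):
        alns = wga.parse_paf(path)
        if config.homologous_regex:
            alns = collinearity.restrict_homologous(alns, config.homologous_regex)
        for aln in alns:
            aln.target_assembly, aln.query_assembly = a, b
        alignments[(a, b)] = alns

    # stage: collinear calling
    pairs: list[CollinearPair] = []
    for (a, b), alns in sorted(alignments.items()):
        pairs.extend(
            call_pair_evidence(
                asm_by_id[a], asm_by_id[b], alns,
                config.overlap_fraction, config.min_coverage,
                config.wga_algorithm,
            )
        )
    wga.write_collinear_tsv(pairs, os.path.join(config.outdir, "collinear.tsv"))

    # stage: clustering
    clusters = clustering.greedy_cluster(pairs, assemblies, config.max_neighbors)
    reference = config.reference_assembly or assemblies[0].assembly_id
    clustering.name_clusters(clusters, reference)
    clustering.attach_sequences(clusters, records, assemblies)
    clustering.flag_structure(clusters, assemblies, config.max_neighbors)
    clusters.sort(key=lambda c: c.cluster_id)
    clustering.write_cluster_fastas(clusters, os.path.join(config.outdir, "clusters"))

    # stage: matrices and reports
    n = len(assemblies)
    occupancy = pangenome_analysis.occupancy_counts(
        clusters, n, config.softcore_fraction)
    matrix = pangenome_analysis.build_pangene_matrix(clusters, assemblies)
    pangenome_analysis.write_pangene_matrix(
        matrix, os.path.join(config.outdir, "pangene_matrix.tsv"))
    pocs = pangenome_analysis.pocs_matrix(clusters, assemblies)
    pocs.to_csv(os.path.join(config.outdir, "pocs.tsv"), sep="\t")
    ani = wga.ani_matrix(alignments, [a.assembly_id for a in assemblies])
    ani.to_csv(os.path.join(config.outdir, "ani.tsv"), sep="\t")
    growth = pangenome_analysis.growth_curves(
        clusters, assemblies, n_perm=config.growth_permutations,
        seed=config.seed, softcore_frac=config.softcore_fraction)
    growth.to_csv(os.path.join(config.outdir, "growth_curves.tsv"),
                  sep="\t", index=False)
    with open(os.path.join(config.outdir, "cluster_report.tsv"), "w") as fh:
        fh.write("#cluster_id\toccupancy\tclass\tsplit\ttandem\tinverted\t"
                 "members\tsegments\n")
        for cl in clusters:
            klass = pangenome_analysis.classify_occupancy(
                cl, n, config.softcore_fraction)
            members = ";".join(
                f"{asm}:{','.join(gids)}" for asm, gids in sorted(cl.members.items())
                if gids)
            segs = ";".join(
                f"{asm}:{seg.id}" for asm in sorted(cl.gdna_members)
                for seg in cl.gdna_members[asm])
            fh.write(f"{cl.cluster_id}\t{cl.occupancy}\t{klass}\t"
                     f"{cl.split_count}\t{cl.tandem_count}\t{cl.inverted_count}\t"
                     f"{members}\t{segs or '-'}\n")

    # stage: lift-over check of candidate missing genes
    occ_min = (config.liftover_occupancy_min
               if config.liftover_occupancy_min is not None else n // 2)
    results = []
    for cl in clusters:
        if not cl.gdna_members or cl.occupancy < occ_min:
            continue
        if not cl.sequences.get("cds"):
            continue
        results.extend(
            liftover.check_cluster(
                cl, assemblies, mode="missing",
                min_query_coverage=config.liftover_min_query_coverage,
            )
        )
    liftover.emit_patch_gff(results, os.path.join(config.outdir, "patch.gff3"))
    with open(os.path.join(config.outdir, "liftover_report.tsv"), "w") as fh:
        fh.write("#cluster_id\ttarget_assembly\tsegment\tverdict\torf_status\t"
                 "matches\tmismatches\tinsertions\tdeletions\tcoverage\n")
        for r in sorted(results, key=lambda r: (r.cluster_id, r.target_assembly)):
            seg = f"{r.segment[0]}:{r.segment[1]}-{r.segment[2]}({r.segment[3]})"
            fh.write(f"{r.cluster_id}\t{r.target_assembly}\t{seg}\t{r.verdict}\t"
                     f"{r.orf_status}\t{r.matches}\t{r.mismatches}\t"
                     f"{r.insertions_bp}\t{r.deletions_bp}\t"
                     f"{r.query_coverage:.4f}\n")

    manifest = {
        "parameters": {
            "overlap_fraction": config.overlap_fraction,
            "min_coverage": config.min_coverage,
            "max_neighbors": config.max_neighbors,
            "min_len": config.min_len,
            "softcore_fraction": config.softcore_fraction,
            "homologous_regex": config.homologous_regex,
            "seed": config.seed,
            "wga_algorithm": config.wga_algorithm,
            "pocs_formula": "100*(g_A+g_B)/(T_A+T_B), g_X = genes of X in "
                            "clusters shared with the partner, T_X = all "
                            "clustered genes of X",
            "ani_note": "length-weighted mean identity over aligned columns",
        },
        "assemblies": [a.assembly_id for a in assemblies],
        "n_pairs": len(pairs),
        "n_clusters": len(clusters),
        "occupancy": occupancy,
        "n_liftover_checks": len(results),
    }
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return PipelineResult(
        config, assemblies, pairs, clusters, occupancy, matrix, pocs, ani,
        growth, results, manifest,
    )
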