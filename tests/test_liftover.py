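"""Consensus selection, spliced alignment and PAV verdict classification."""

import numpy as np
import pytest
from Bio.Seq import Seq

from pangenewga.annotation_io import SequenceRecord
from pangenewga.clustering import PangeneCluster
from pangenewga.collinearity import Member
from pangenewga.liftover import (
    check_cluster,
    consensus_isoforms,
    emit_patch_gff,
    orf_status,
    spliced_align,
)

from conftest import make_assembly, make_gene


def _rec(seq, seq_id="r", kind="cds", assembly="A", gene="g"):
    return SequenceRecord(seq_id, kind, seq, ("c1", 0, len(seq), "+"),
                          gene, seq_id + ".t", assembly)


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _random_cds(rng, n_codons):
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3)
        if c not in stops:
            codons.append(c)
    return "".join(codons) + "TAA"


def _plant(rng, cds, exon_lens, flank=400):
    """Embed a CDS as exons separated by GT..AG introns; return
    (segment_sequence, expected exon blocks)."""
    parts = [_random_seq(rng, flank)]
    pos = flank
    blocks = []
    off = 0
    for i, L in enumerate(exon_lens):
        parts.append(cds[off : off + L])
        blocks.append((pos, pos + L))
        pos += L
        off += L
        if i < len(exon_lens) - 1:
            intron = "GT" + _random_seq(rng, 80) + "AG"
            parts.append(intron)
            pos += len(intron)
    parts.append(_random_seq(rng, flank))
    return "".join(parts), blocks


class TestConsensus:
    def _cluster(self, lengths):
        cl = PangeneCluster("c", {"A": ["g"]})
        cl.sequences = {"cds": [_rec("A" * L, f"r{i}")
                                for i, L in enumerate(lengths)]}
        return cl

    def test_outlier_threshold_both_ways(self):
        cl = self._cluster([300, 300, 300, 150])
        cs = consensus_isoforms(cl, outlier_frac=0.5)
        assert len(cs.consensus_isoforms) == 4 and not cs.outliers
        cs = consensus_isoforms(cl, outlier_frac=0.4)
        assert len(cs.outliers) == 1 and len(cs.outliers[0]) == 150

    def test_all_identical_no_outliers(self):
        cs = consensus_isoforms(self._cluster([200] * 5))
        assert not cs.outliers and cs.mode_length == 200

    def test_tie_prefers_longest(self):
        cs = consensus_isoforms(self._cluster([300, 300, 600, 600]))
        assert cs.mode_length == 600

    def test_no_cds_is_error(self):
        cl = PangeneCluster("c", {"A": ["g"]})
        cl.sequences = {"cds": []}
        with pytest.raises(ValueError, match="no coding evidence"):
            consensus_isoforms(cl)


class TestSplicedAlign:
    def test_exact_three_exon_recovery(self, rng):
        cds = _random_cds(rng, 140)  # 420 bp
        seg, blocks = _plant(rng, cds, [140, 140, 140])
        aln = spliced_align(cds, seg)
        assert aln is not None
        assert aln.exon_blocks == blocks
        assert (aln.matches, aln.mismatches) == (len(cds), 0)
        assert aln.insertions_bp == aln.deletions_bp == 0
        assert aln.query_coverage == 1.0
        assert aln.spliced_seq == cds

    def test_micro_exon_below_seed_size_recovered(self, rng):
        # a 7 bp internal exon cannot anchor a seed chain; it must be
        # rescued by exact search between the flanking exons
        cds = _random_cds(rng, 100)  # 300 bp
        seg, blocks = _plant(rng, cds, [150, 7, 143])
        aln = spliced_align(cds, seg)
        assert aln is not None
        assert aln.exon_blocks == blocks
        assert aln.query_coverage == 1.0 and aln.mismatches == 0
        assert aln.insertions_bp == 0 and aln.deletions_bp == 0

    def test_absent_query_returns_none(self, rng):
        cds = _random_cds(rng, 100)
        seg = _random_seq(rng, 2000)
        assert spliced_align(cds, seg) is None

    def test_single_substitution_counted(self, rng):
        cds = _random_cds(rng, 120)
        seg, _ = _plant(rng, cds, [180, 180])
        mutated = list(cds)
        mutated[90] = "C" if cds[90] != "C" else "G"
        aln = spliced_align("".join(mutated), seg)
        assert aln.matches == len(cds) - 1 and aln.mismatches == 1

    def test_reverse_strand_hint(self, rng):
        cds = _random_cds(rng, 110)
        seg, blocks = _plant(rng, cds, [165, 165])
        rc = str(Seq(seg).reverse_complement())
        aln = spliced_align(cds, rc, strand_hint="-")
        L = len(seg)
        assert aln is not None and aln.strand == "-"
        assert sorted((L - e, L - s) for s, e in blocks) == aln.exon_blocks
        assert aln.mismatches == 0 and aln.query_coverage == 1.0

    def test_orf_status_matches_translation_oracle(self, rng):
        for trial in range(10):
            cds = _random_cds(rng, int(rng.integers(80, 150)))
            seg, _ = _plant(rng, cds, [len(cds) // 2, len(cds) - len(cds) // 2])
            aln = spliced_align(cds, seg)
            status = orf_status(aln)
            pep = str(Seq(aln.spliced_seq).translate())
            oracle_intact = (
                aln.spliced_seq.startswith("ATG")
                and len(aln.spliced_seq) % 3 == 0
                and pep.endswith("*")
                and "*" not in pep[:-1]
            )
            assert (status == "intact") == oracle_intact


class TestCheckCluster:
    def _build(self, rng, hide=True, delete_prefix=False):
        """Cluster of 3 donor genes + segment member in assembly X where the
        gene is unannotated (hidden) or partially deleted."""
        cds = _random_cds(rng, 150)  # 450 bp
        chrom, blocks = _plant(rng, cds, [150, 150, 150], flank=600)
        if delete_prefix:
            # remove exons 1-2 with their introns; the last exon survives
            chrom = chrom[: blocks[0][0]] + chrom[blocks[2][0] :]
            blocks = None
        asm_x = make_assembly("X", {"c1": chrom}, [])
        cl = PangeneCluster("clu", {"A": ["gA"], "B": ["gB"], "C": ["gC"],
                                    "X": []})
        cl.sequences = {"cds": [_rec(cds, f"g{a}:t", assembly=a, gene=f"g{a}")
                                for a in "ABC"]}
        lo, hi = 550, len(chrom) - 550
        cl.gdna_members = {"X": [Member.segment("X", "c1", lo, hi, "+")]}
        return cl, asm_x, cds, blocks

    def test_hidden_gene_confirmed_with_exact_exons(self, rng):
        cl, asm_x, cds, blocks = self._build(rng)
        results = check_cluster(cl, [asm_x], mode="missing")
        assert len(results) == 1
        r = results[0]
        assert r.verdict == "missing_gene_confirmed"
        assert r.orf_status == "intact"
        assert r.mismatches == 0 and r.insertions_bp == 0
        assert r.exon_blocks == blocks

    def test_partial_deletion_rejected_as_partial(self, rng):
        cl, asm_x, cds, _ = self._build(rng, delete_prefix=True)
        results = check_cluster(cl, [asm_x], mode="missing")
        assert len(results) == 1
        assert results[0].verdict == "rejected"
        assert results[0].orf_status == "partial"

    def test_split_mode_fix(self, rng):
        cds = _random_cds(rng, 150)
        seg, blocks = _plant(rng, cds, [225, 225], flank=600)
        asm_x = make_assembly(
            "X", {"c1": seg},
            [make_gene("x1", "c1", blocks[0][0], blocks[0][1]),
             make_gene("x2", "c1", blocks[1][0], blocks[1][1])])
        cl = PangeneCluster("clu", {"A": ["gA"], "X": ["x1", "x2"]})
        cl.sequences = {"cds": [_rec(cds, "gA:t", assembly="A", gene="gA")]}
        results = check_cluster(cl, [asm_x], mode="split")
        assert len(results) == 1 and results[0].verdict == "split_fix"


class TestPatchGff:
    def test_confirmed_three_exon_block_structure(self, rng, tmp_path):
        cds = _random_cds(rng, 140)
        seg, blocks = _plant(rng, cds, [140, 140, 140], flank=500)
        asm_x = make_assembly("X", {"c1": seg}, [])
        cl = PangeneCluster("clu", {"A": ["gA"], "X": []})
        cl.sequences = {"cds": [_rec(cds, "gA:t", assembly="A", gene="gA")]}
        cl.gdna_members = {"X": [Member.segment("X", "c1", 500,
                                                len(seg) - 500, "+")]}
        results = check_cluster(cl, [asm_x], mode="missing")
        path = tmp_path / "patch.gff3"
        n = emit_patch_gff(results, str(path))
        assert n == 1
        lines = [l.split("\t") for l in path.read_text().splitlines()
                 if not l.startswith("#")]
        types = [l[2] for l in lines]
        assert types == ["gene", "mRNA"] + ["exon"] * 3 + ["CDS"] * 3
        exon_lines = [l for l in lines if l[2] == "exon"]
        got = [(int(l[3]) - 1, int(l[4])) for l in exon_lines]
        assert got == blocks  # exact planted coordinates, 1-based in file

    def test_rejected_results_never_written(self, rng, tmp_path):
        cds = _random_cds(rng, 120)
        seg, _ = _plant(rng, cds, [360])
        asm_x = make_assembly("X", {"c1": seg}, [])
        cl = PangeneCluster("clu", {"A": ["gA"], "X": []})
        # mutated consensus -> premature stop after liftover is impossible;
        # use a truncated query so coverage stays below 1
        cl.sequences = {"cds": [_rec(cds[: len(cds) // 2] + "ACGTACGTAC",
                                     "gA:t", assembly="A", gene="gA")]}
        cl.gdna_members = {"X": [Member.segment("X", "c1", 400,
                                                len(seg) - 400, "+")]}
        results = check_cluster(cl, [asm_x], mode="missing")
        assert all(r.verdict == "rejected" for r in results)
        path = tmp_path / "patch.gff3"
        assert emit_patch_gff(results, str(path)) == 0
        assert path.read_text() == "##gff-version 3\n"
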