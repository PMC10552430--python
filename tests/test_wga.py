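"""PAF parsing, CIGAR/segment decomposition, identity and the evidence TSV."""

import numpy as np
import pytest

from pangenewga import wga
from pangenewga.collinearity import CollinearPair, Member
from pangenewga.wga import (
    PafError,
    WgaAlignment,
    alignment_identity,
    ani_matrix,
    cigar_to_segments,
    cs_to_cigar,
    parse_paf_with_report,
    read_collinear_tsv,
    tsv_to_paf,
    write_collinear_tsv,
)

from conftest import per_base_map, random_alignment


def _paf_line(qs=0, qe=100, ts=0, te=100, strand="+", tags=("cg:Z:100M",)):
    cols = ["q", "200", str(qs), str(qe), strand, "t", "200", str(ts), str(te),
            "100", "100", "60", *tags]
    return "\t".join(cols)


class TestParsePaf:
    def test_basic_line(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text(_paf_line() + "\n")
        alns, rejected = parse_paf_with_report(str(p))
        assert len(alns) == 1 and not rejected
        assert alns[0].cigar == "100M"

    def test_span_mismatch_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text(_paf_line() + "\n" +
                     _paf_line(tags=("cg:Z:50M10I50M",)) + "\n")
        alns, rejected = parse_paf_with_report(str(p))
        assert len(alns) == 1
        assert len(rejected) == 1 and "line 2" in rejected[0]

    def test_missing_cigar_and_secondary_rejected(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text(_paf_line(tags=()) + "\n" +
                     _paf_line(tags=("cg:Z:100M", "tp:A:S")) + "\n")
        alns, rejected = parse_paf_with_report(str(p))
        assert not alns and len(rejected) == 2

    def test_cs_tag_accepted(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text(_paf_line(tags=("cs:Z::100",)) + "\n")
        alns, _ = parse_paf_with_report(str(p))
        assert alns[0].cigar == "100="


class TestCsToCigar:
    def test_substitution(self):
        assert cs_to_cigar(":50*at:49") == "50=1X49="

    def test_indels(self):
        assert cs_to_cigar(":10+acg:5-tt:3") == "10=3I5=2D3="

    def test_cs_and_cg_give_same_per_base_map(self, rng):
        # oracle: both encodings of one alignment map bases identically
        cs = ":30*ac:9+acgt:20-tg:40"
        cigar = cs_to_cigar(cs)
        aln = WgaAlignment("q", 200, 0, 104, "+", "t", 200, 0, 102, cigar)
        aln.validate()
        m = per_base_map(aln)
        # manual walk of the cs string
        expect = {}
        q = t = 0
        for span in [(30, True), (1, True), (9, True)]:
            for _ in range(span[0]):
                expect[q] = t
                q += 1
                t += 1
        q += 4  # +acgt
        for _ in range(20):
            expect[q] = t
            q += 1
            t += 1
        t += 2  # -tg
        for _ in range(40):
            expect[q] = t
            q += 1
            t += 1
        assert m == expect


class TestCigarToSegments:
    def test_identity(self):
        aln = WgaAlignment("q", 100, 0, 100, "+", "t", 100, 0, 100, "100M")
        segs = cigar_to_segments(aln)
        assert len(segs) == 1
        assert (segs[0].query_start, segs[0].query_end) == (0, 100)
        assert (segs[0].target_start, segs[0].target_end) == (0, 100)

    def test_deletion_splits_segments(self):
        aln = WgaAlignment("q", 100, 0, 100, "+", "t", 110, 0, 110, "40M10D60M")
        segs = cigar_to_segments(aln)
        assert [(s.query_start, s.query_end, s.target_start, s.target_end)
                for s in segs] == [(0, 40, 0, 40), (40, 100, 50, 110)]

    def test_unsupported_op(self):
        aln = WgaAlignment("q", 100, 0, 100, "+", "t", 100, 0, 100, "100M")
        aln.cigar = "50M10N50M"
        with pytest.raises(PafError, match="N"):
            cigar_to_segments(aln)

    def test_minus_strand_insertion_example(self):
        aln = WgaAlignment("q", 65, 0, 65, "-", "t", 60, 0, 60, "30M5I30M")
        segs = cigar_to_segments(aln)
        covered = set()
        for s in segs:
            covered.update(range(s.query_start, s.query_end))
        assert covered == set(range(0, 30)) | set(range(35, 65))
        assert per_base_map(aln) == {
            q: s.map_query_to_target(q)
            for s in segs for q in range(s.query_start, s.query_end)
        }

    def test_equivalence_with_per_base_oracle_on_random_cigars(self):
        rng = np.random.default_rng(99)
        for _ in range(300):
            aln = random_alignment(rng, max_len=2000)
            segs = cigar_to_segments(aln)
            oracle = per_base_map(aln)
            got = {q: s.map_query_to_target(q)
                   for s in segs for q in range(s.query_start, s.query_end)}
            assert got == oracle
            # conservation: total segment length equals aligned columns
            assert sum(len(s) for s in segs) == aln.aligned_columns
            # segments ordered and non-overlapping along the target
            for s1, s2 in zip(segs, segs[1:]):
                assert s1.target_end <= s2.target_start


class TestIdentity:
    def test_extended_cigars(self):
        a = WgaAlignment("q", 100, 0, 100, "+", "t", 100, 0, 100, "100=")
        assert alignment_identity(a) == 100.0
        b = WgaAlignment("q", 100, 0, 100, "+", "t", 100, 0, 100, "95=5X")
        assert alignment_identity(b) == 95.0

    def test_m_ops_resolved_by_sequences(self):
        q = "A" * 49 + "C" + "A" * 0
        t = "A" * 50
        a = WgaAlignment("q", 50, 0, 50, "+", "t", 50, 0, 50, "50M")
        assert alignment_identity(a, q, t) == pytest.approx(98.0)

    def test_m_ops_without_sequences_error(self):
        a = WgaAlignment("q", 50, 0, 50, "+", "t", 50, 0, 50, "50M")
        with pytest.raises(PafError, match="identity unresolved"):
            alignment_identity(a)

    def test_ani_weighted_mean_and_missing_pair(self):
        a100 = WgaAlignment("q", 100, 0, 100, "+", "t", 100, 0, 100, "100=")
        a90 = WgaAlignment("q", 100, 0, 100, "+", "t", 100, 0, 100, "90=10X")
        mat = ani_matrix({("A", "B"): [a100, a90], ("A", "C"): []},
                         ["A", "B", "C"])
        assert mat.loc["A", "B"] == pytest.approx(95.0)
        assert mat.loc["B", "A"] == pytest.approx(95.0)
        assert np.isnan(mat.loc["A", "C"])
        assert mat.loc["C", "C"] == 100.0


def _random_pairs(rng, n):
    pairs = []
    for i in range(n):
        kind = "gene-gene" if rng.random() < 0.8 else "gene-gdna"
        a = Member(f"ga{i}", "A", "chr1", int(rng.integers(0, 1000)),
                   int(rng.integers(1000, 2000)), "+")
        if kind == "gene-gene":
            b = Member(f"gb{i}", "B", "chr1", 5, 500, "-")
        else:
            b = Member.segment("B", "chr2", 100, 900, "+")
        pairs.append(CollinearPair(a, b, int(rng.integers(1, 2000)),
                                   "minimap2", bool(rng.random() < 0.3), kind))
    return pairs


class TestCollinearTsv:
    def test_round_trip(self, tmp_path, rng):
        pairs = _random_pairs(rng, 200)
        p = tmp_path / "ev.tsv"
        write_collinear_tsv(pairs, str(p))
        back = read_collinear_tsv(str(p))
        assert back == pairs

    def test_byte_stable_after_rewrite(self, tmp_path, rng):
        pairs = _random_pairs(rng, 50)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_collinear_tsv(pairs, str(p1))
        write_collinear_tsv(read_collinear_tsv(str(p1)), str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_list_header_only(self, tmp_path):
        p = tmp_path / "ev.tsv"
        write_collinear_tsv([], str(p))
        lines = p.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("#")

    def test_unknown_pair_type_rejected(self, tmp_path):
        p = tmp_path / "ev.tsv"
        row = ["g1", "A", "chr1", "0", "100", "+", "g2", "B", "chr1", "0",
               "100", "+", "2400", "minimap2", "0", "gene-protein"]
        p.write_text("#" + "\t".join(wga.TSV_COLUMNS) + "\n"
                     + "\t".join(row) + "\n")
        with pytest.raises(PafError, match="pair_type"):
            read_collinear_tsv(str(p))

    def test_hand_written_overlap_field(self, tmp_path):
        row = ["ONIVA01G00130", "nivara", "1", "0", "5000", "+",
               "Os01g0100500", "sativa", "1", "0", "5000", "+",
               "2400", "minimap2", "0", "gene-gene"]
        p = tmp_path / "ev.tsv"
        p.write_text("\t".join(row) + "\n")
        pairs = read_collinear_tsv(str(p))
        assert pairs[0].overlap_bp == 2400


class TestTsvToPaf:
    def test_gene_gene_only_with_strand_from_inversion(self, tmp_path, rng):
        pairs = _random_pairs(rng, 40)
        tsv = tmp_path / "ev.tsv"
        out = tmp_path / "ev.paf"
        write_collinear_tsv(pairs, str(tsv))
        n = tsv_to_paf(str(tsv), str(out))
        gene_gene = [p for p in pairs if p.pair_type == "gene-gene"]
        lines = out.read_text().splitlines()
        assert n == len(gene_gene) == len(lines)
        for p, line in zip(gene_gene, lines):
            cols = line.split("\t")
            assert cols[4] == ("-" if p.inverted else "+")
            assert cols[12].startswith("cg:Z:")
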