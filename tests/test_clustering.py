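"""Greedy clustering under the neighbor-distance constraint, naming,
sequence attachment and structure flags."""

import numpy as np
import pytest

from pangenewga.clustering import (
    PangeneCluster,
    attach_sequences,
    flag_structure,
    greedy_cluster,
    name_clusters,
    write_cluster_fastas,
)
from pangenewga.annotation_io import cut_sequences
from pangenewga.collinearity import CollinearPair, Member

from conftest import make_assembly, make_gene


def _asm(assembly_id, gene_specs, chrom="c1", seq_len=200_000):
    """gene_specs: list of (gene_id, start) or (gene_id, start, chrom)."""
    chroms: dict[str, str] = {}
    genes = []
    for spec in gene_specs:
        gid, start = spec[0], spec[1]
        c = spec[2] if len(spec) > 2 else chrom
        chroms.setdefault(c, "A" * seq_len)
        genes.append(make_gene(gid, c, start, start + 500))
    chroms.setdefault(chrom, "A" * seq_len)
    return make_assembly(assembly_id, chroms, genes)


def _pair(a, asm_a, b, asm_b, overlap=400, inverted=False, rank_pos=None):
    ma = Member(a, asm_a, "c1", 0, 500, "+")
    mb = Member(b, asm_b, "c1", 0, 500, "+")
    return CollinearPair(ma, mb, overlap, "simulated", inverted, "gene-gene")


class TestGreedyCluster:
    def test_single_pair_occupancy_two(self):
        A = _asm("A", [("a1", 1000)])
        B = _asm("B", [("b1", 1000)])
        clusters = greedy_cluster([_pair("a1", "A", "b1", "B")], [A, B])
        assert len(clusters) == 1
        assert clusters[0].occupancy == 2

    @pytest.mark.parametrize("max_neighbors,joined", [(5, False), (7, True)])
    def test_neighbor_distance_constraint(self, max_neighbors, joined):
        # sp2 candidate sits 7 ranks from the clustered sp2 gene: 6
        # intervening genes, excluded at N=5, included at N=7
        B = _asm("B", [(f"b{i}", 1000 * (i + 1)) for i in range(8)])
        A = _asm("A", [("a1", 1000)])
        pairs = [_pair("a1", "A", "b0", "B"), _pair("a1", "A", "b7", "B", 300)]
        clusters = greedy_cluster(pairs, [A, B], max_neighbors=max_neighbors)
        cl = next(c for c in clusters if "b0" in c.members["B"])
        assert ("b7" in cl.members["B"]) is joined

    def test_tandem_neighbors_join(self):
        A = _asm("A", [("a1", 1000), ("a2", 2000)])
        B = _asm("B", [("b1", 1000)])
        pairs = [_pair("a1", "A", "b1", "B"), _pair("a2", "A", "b1", "B", 300)]
        clusters = greedy_cluster(pairs, [A, B])
        cl = next(c for c in clusters if c.members["B"])
        assert cl.members["A"] == ["a1", "a2"]

    def test_cross_chromosome_merge_refused(self):
        # two same-assembly genes on different chromosomes linked via B
        A = _asm("A", [("a1", 1000, "c1"), ("a2", 1000, "c2")])
        B = _asm("B", [("b1", 1000)])
        pairs = [_pair("a1", "A", "b1", "B"), _pair("a2", "A", "b1", "B", 300)]
        clusters = greedy_cluster(pairs, [A, B])
        cl = next(c for c in clusters if c.members["B"])
        assert cl.members["A"] in (["a1"], ["a2"])
        assert len(clusters) == 2  # the refused gene seeds its own cluster

    def test_unknown_gene_raises(self):
        A = _asm("A", [("a1", 1000)])
        B = _asm("B", [("b1", 1000)])
        with pytest.raises(KeyError, match="zz"):
            greedy_cluster([_pair("zz", "A", "b1", "B")], [A, B])

    def test_every_gene_in_exactly_one_cluster(self):
        A = _asm("A", [(f"a{i}", 1000 * (i + 1)) for i in range(10)])
        B = _asm("B", [(f"b{i}", 1000 * (i + 1)) for i in range(10)])
        pairs = [_pair(f"a{i}", "A", f"b{i}", "B") for i in range(5)]
        clusters = greedy_cluster(pairs, [A, B])
        seen = []
        for cl in clusters:
            for asm, gids in cl.members.items():
                seen += [(asm, g) for g in gids]
        assert sorted(seen) == sorted(
            [("A", f"a{i}") for i in range(10)] +
            [("B", f"b{i}") for i in range(10)])

    def test_order_invariance_and_posthoc_constraint(self):
        rng = np.random.default_rng(3)
        A = _asm("A", [(f"a{i}", 1000 * (i + 1)) for i in range(30)])
        B = _asm("B", [(f"b{i}", 1000 * (i + 1)) for i in range(30)])
        pairs = []
        for _ in range(60):
            i, j = int(rng.integers(0, 30)), int(rng.integers(0, 30))
            pairs.append(_pair(f"a{i}", "A", f"b{j}", "B",
                               overlap=int(rng.integers(100, 500))))
        c1 = greedy_cluster(pairs, [A, B], max_neighbors=3)
        shuffled = list(pairs)
        rng.shuffle(shuffled)
        c2 = greedy_cluster(shuffled, [A, B], max_neighbors=3)
        sig = lambda cs: sorted(tuple(sorted(
            (a, g) for a, gs in c.members.items() for g in gs)) for c in cs)
        assert sig(c1) == sig(c2)
        # post-hoc: no cluster violates the diameter constraint
        rank = {("A", f"a{i}"): i for i in range(30)}
        rank.update({("B", f"b{i}"): i for i in range(30)})
        for cl in c1:
            for asm, gids in cl.members.items():
                ranks = [rank[(asm, g)] for g in gids]
                if len(ranks) > 1:
                    assert max(ranks) - min(ranks) - 1 <= 3

    def test_minority_orientation_flagged(self):
        A = _asm("A", [("a1", 1000)])
        B = _asm("B", [("b1", 1000)])
        C = _asm("C", [("c1", 1000)])
        pairs = [
            _pair("a1", "A", "b1", "B", 400, inverted=False),
            _pair("a1", "A", "c1", "C", 350, inverted=True),
            _pair("b1", "B", "c1", "C", 300, inverted=True),
        ]
        clusters = greedy_cluster(pairs, [A, B, C])
        assert clusters[0].inverted_members == {"c1"}


class TestNameClusters:
    def _cluster(self, members):
        return PangeneCluster("", members)

    def test_reference_member_names_cluster(self):
        cl = self._cluster({"REF": ["R1"], "B": ["zz9"]})
        name_clusters([cl], "REF")
        assert cl.cluster_id == "R1"

    def test_fallback_lexicographic(self):
        cl = self._cluster({"A": ["zz9"], "B": ["aa1"]})
        name_clusters([cl], "REF")
        assert cl.cluster_id == "aa1"

    def test_duplicate_names_suffixed(self):
        c1 = self._cluster({"A": ["aa1"]})
        c2 = self._cluster({"B": ["aa1"]})
        name_clusters([c1, c2], None)
        assert {c1.cluster_id, c2.cluster_id} == {"aa1", "aa1_2"}


class TestSequencesAndFlags:
    def test_attach_and_write(self, toy_assembly, tmp_path):
        recs = cut_sequences(toy_assembly, min_len=50)
        cl = PangeneCluster("gA", {"T1": ["gA", "gC"]})
        attach_sequences([cl], recs, [toy_assembly])
        assert len(cl.sequences["cdna"]) == 2
        write_cluster_fastas([cl], str(tmp_path))
        text = (tmp_path / "gA.cdna.fna").read_text()
        assert text.count(">") == 2

    def test_member_without_sequence_reported(self, toy_assembly):
        recs = [r for r in cut_sequences(toy_assembly, min_len=50)
                if r.gene_id != "gC"]
        cl = PangeneCluster("gA", {"T1": ["gA", "gC"]})
        attach_sequences([cl], recs)
        assert cl.missing_sequence_members == ["T1:gC"]

    def test_gdna_member_sequence_cut(self, toy_assembly):
        cl = PangeneCluster("gA", {"T1": ["gA"]},
                            gdna_members={"T1": [Member.segment(
                                "T1", "chr1", 100, 700, "+")]})
        attach_sequences([cl], cut_sequences(toy_assembly, min_len=50),
                         [toy_assembly])
        assert len(cl.sequences["gdna"]) == 1
        assert cl.sequences["gdna"][0].sequence == \
            toy_assembly.chromosomes["chr1"][100:700]

    def _flag_fixture(self, n_full, split_lens=None, tandem=False):
        """n_full assemblies with one 300bp-CDS gene; one extra assembly with
        either split fragments or a tandem duplicate."""
        assemblies, clusters_members = [], {}
        for i in range(n_full):
            aid = f"F{i}"
            assemblies.append(_asm(aid, [(f"g{aid}", 1000)]))
            # replace gene with one of CDS length 300
            asm = assemblies[-1]
            g = asm.gene_index["c1"][0]
            g.transcripts[0].exons = [(1000, 1300)]
            g.transcripts[0].cds_segments = [(1000, 1300, 0)]
            clusters_members[aid] = [f"g{aid}"]
        extra = "XX"
        if split_lens:
            specs = [(f"s{k}", 1000 + 400 * k) for k in range(len(split_lens))]
            asm = _asm(extra, specs)
            for g, L in zip(asm.gene_index["c1"], split_lens):
                g.transcripts[0].exons = [(g.start, g.start + L)]
                g.transcripts[0].cds_segments = [(g.start, g.start + L, 0)]
            assemblies.append(asm)
            clusters_members[extra] = [s[0] for s in specs]
        cl = PangeneCluster("c", clusters_members)
        return cl, assemblies

    def test_split_models_counted(self):
        cl, assemblies = self._flag_fixture(3, split_lens=[150, 150])
        flag_structure([cl], assemblies)
        assert cl.split_count == 1 and cl.tandem_count == 0

    def test_tandem_copies_counted(self):
        cl, assemblies = self._flag_fixture(3, split_lens=[300, 300])
        flag_structure([cl], assemblies)
        assert cl.tandem_count == 1 and cl.split_count == 0
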