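"""Clustering, pairwise mutational distances, MST construction and export."""
import itertools

import networkx as nx
import numpy as np
import pytest

from satlib import (HapRow, ParameterError, build_mst, export_graph,
                    greedy_cluster, pairwise_differences,
                    same_species_edge_fraction, species_coherence_test)
from satlib.hapnet import load_graph

from oracles import min_spanning_tree_weight, random_dna


def _row(seq, count=1, hid=None, species="sp", origin="illumina"):
    return HapRow(hid or f"h{abs(hash(seq)) % 10**6}", seq, count, species, origin)


class TestGreedyCluster:
    def test_identical_sequences_collapse_with_summed_abundance(self):
        rows = [_row("ACGT" * 50, count=c, hid=f"h{i}", species=f"sp{i}")
                for i, c in enumerate((5, 3, 2))]
        cs = greedy_cluster(rows, threshold=0.99)
        assert len(cs) == 1
        assert cs.clusters[0].abundance == 10
        assert sorted(cs.clusters[0].member_ids) == ["h0", "h1", "h2"]

    def test_identity_boundary_around_99_percent(self, rng):
        base = random_dna(rng, 200)
        one_diff = "T" + base[1:] if base[0] != "T" else "A" + base[1:]
        three = list(base)
        for pos, alt in ((0, "T"), (50, "T"), (100, "T")):
            three[pos] = alt if base[pos] != alt else "A"
        three_diff = "".join(three)
        # 199/200 = 0.995 >= 0.99 -> one cluster
        cs1 = greedy_cluster([_row(base, 5, "a"), _row(one_diff, 1, "b")], 0.99)
        assert len(cs1) == 1
        # 197/200 = 0.985 < 0.99 -> two clusters
        cs2 = greedy_cluster([_row(base, 5, "a"), _row(three_diff, 1, "b")], 0.99)
        assert len(cs2) == 2

    def test_threshold_one_equals_exact_deduplication(self, rng):
        seqs = [random_dna(rng, 60) for _ in range(5)]
        rows = [_row(s, hid=f"h{i}") for i, s in enumerate(seqs + seqs[:2])]
        cs = greedy_cluster(rows, threshold=1.0)
        assert len(cs) == len(set(seqs + seqs[:2]))

    def test_lowering_threshold_never_increases_cluster_count(self, consensus, rng):
        c = consensus.sequence
        rows = []
        for i in range(10):
            s = "".join(x if rng.random() > 0.03 else "ACGT"[rng.integers(0, 4)]
                        for x in c)
            rows.append(_row(s, count=int(rng.integers(1, 6)), hid=f"h{i}"))
        sizes = [len(greedy_cluster(rows, t)) for t in (1.0, 0.99, 0.97, 0.90)]
        assert sizes == sorted(sizes, reverse=True)

    def test_members_meet_threshold_to_representative(self, consensus, rng):
        from satlib._align import global_aligner, global_identity
        c = consensus.sequence
        rows = [_row("".join(x if rng.random() > 0.02 else "ACGT"[rng.integers(0, 4)]
                             for x in c), hid=f"h{i}") for i in range(8)]
        cs = greedy_cluster(rows, 0.98)
        aligner = global_aligner()
        by_id = {r.haplotype_id: r.sequence for r in rows}
        assert sorted(m for cl in cs.clusters for m in cl.member_ids) == \
            sorted(by_id)
        for cl in cs.clusters:
            for m in cl.member_ids:
                assert global_identity(by_id[m], cl.representative_seq,
                                       aligner) >= 0.98

    def test_empty_input_gives_empty_set(self):
        assert len(greedy_cluster([], 0.99)) == 0

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ParameterError):
            greedy_cluster([], 0.0)


class TestPairwiseDifferences:
    def test_identical_rows(self):
        assert pairwise_differences(["ACGT", "ACGT"])[0, 1] == 0

    def test_single_substitution(self):
        assert pairwise_differences(["ACGT", "ACCT"])[0, 1] == 1

    def test_gap_run_counts_once(self):
        assert pairwise_differences(["AC--GT", "ACTTGT"])[0, 1] == 1

    def test_matrix_is_symmetric_with_zero_diagonal(self, rng):
        rows = ["".join(rng.choice(list("ACGT-"), 20)) for _ in range(5)]
        d = pairwise_differences(rows)
        assert (d == d.T).all() and (np.diag(d) == 0).all() and (d >= 0).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            pairwise_differences(["ACGT", "ACG"])


class TestBuildMst:
    def test_distance_three_expands_to_two_step_nodes(self):
        d = np.array([[0, 3], [3, 0]])
        mst = build_mst(d, ["a", "b"])
        assert len(mst.step_nodes()) == 2
        assert nx.shortest_path_length(mst.graph, "a", "b") == 3
        assert mst.total_weight == 3

    def test_triangle_selects_two_lightest_edges(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        mst = build_mst(d, ["A", "B", "C"])
        assert sorted((u, v) for u, v, _ in mst.weighted_edges) == \
            [("A", "B"), ("A", "C")]
        assert mst.total_weight == 3
        assert mst.total_weight == min_spanning_tree_weight(d.tolist())

    def test_single_haplotype(self):
        mst = build_mst(np.zeros((1, 1)), ["only"])
        assert mst.weighted_edges == [] and len(mst.graph) == 1

    def test_edge_and_node_counts_after_expansion(self, rng):
        n = 6
        d = rng.integers(1, 6, (n, n))
        d = np.triu(d, 1) + np.triu(d, 1).T
        labels = [f"h{i}" for i in range(n)]
        mst = build_mst(d, labels)
        assert len(mst.weighted_edges) == n - 1
        extra = sum(w - 1 for _, _, w in mst.weighted_edges)
        assert len(mst.graph) == n + extra
        assert mst.graph.number_of_edges() == sum(w for _, _, w in mst.weighted_edges)

    @pytest.mark.parametrize("seed", range(8))
    def test_weight_is_minimal_by_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        d = rng.integers(0, 9, (n, n))
        d = np.triu(d, 1) + np.triu(d, 1).T
        mst = build_mst(d, [f"h{i}" for i in range(n)])
        assert mst.total_weight == min_spanning_tree_weight(d.tolist())

    def test_deterministic_under_ties(self):
        d = np.ones((4, 4), dtype=int) - np.eye(4, dtype=int)
        labels = ["d", "b", "a", "c"]
        m1 = build_mst(d, labels)
        m2 = build_mst(d, labels)
        assert m1.weighted_edges == m2.weighted_edges
        # lexicographic tie-break: all edges anchored at "a"
        assert all("a" in (u, v) for u, v, _ in m1.weighted_edges)


class TestExportGraph:
    def test_round_trip_preserves_nodes_edges_and_attributes(self, tmp_path):
        d = np.array([[0, 2, 4], [2, 0, 5], [4, 5, 0]])
        attrs = {"A": {"species": "sp1", "origin": "illumina", "abundance": 7},
                 "B": {"species": "sp2", "origin": "pcr", "abundance": 1},
                 "C": {"species": "sp1", "origin": "illumina", "abundance": 2}}
        mst = build_mst(d, ["A", "B", "C"], attrs)
        gml = tmp_path / "mst.gml"
        table = tmp_path / "nodes.tsv"
        export_graph(mst, gml, table)
        loaded = load_graph(gml)
        assert set(loaded.nodes) == set(mst.graph.nodes)
        assert set(map(frozenset, loaded.edges)) == set(map(frozenset, mst.graph.edges))
        assert loaded.nodes["A"]["abundance"] == 7
        assert loaded.nodes["B"]["origin"] == "pcr"
        n_lines = table.read_text().strip().split("\n")
        assert len(n_lines) - 1 == len(mst.graph)


class TestSpeciesCoherence:
    def test_homogenized_species_group_together(self, rng):
        # two species with tight within-species clusters of haplotypes
        centers = [random_dna(rng, 120), random_dna(rng, 120)]
        rows, labels, attrs = [], [], {}
        for s, center in enumerate(centers):
            for i in range(6):
                seq = list(center)
                for pos in rng.integers(0, 120, 2):
                    seq[pos] = "ACGT"[rng.integers(0, 4)]
                lab = f"sp{s}_h{i}"
                labels.append(lab)
                rows.append("".join(seq))
                attrs[lab] = {"species": f"sp{s}", "origin": "illumina",
                              "abundance": 1}
        d = pairwise_differences(rows)
        mst = build_mst(d, labels, attrs)
        frac, p = species_coherence_test(mst, n_permutations=999, seed=1)
        assert frac > 0.8
        assert p < 0.05
        assert frac == same_species_edge_fraction(mst)
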