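import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import floyd_warshall, hamming, p_distance
from mothwing.molecular import (
    BarcodeAlignment,
    Haplotype,
    _msn_edges,
    collapse_haplotypes,
    group_distance_summary,
    k2p_distance,
    k2p_matrix,
    median_joining,
    network_stats,
    read_alignment,
    write_nexus_network,
)


def aln(records, groups=None):
    groups = groups or {i: "g" for i in records}
    return BarcodeAlignment(records=records, groups=groups)


class TestReadAlignment:
    def test_three_records(self, tmp_path):
        fa = tmp_path / "a.fasta"
        fa.write_text(">a\nACGT\n>b\nACGA\n>c\nACTT\n")
        gm = tmp_path / "g.csv"
        gm.write_text("id,group\na,x\nb,x\nc,y\n")
        out = read_alignment(fa, gm)
        assert len(out.records) == 3
        assert out.groups["c"] == "y"

    def test_ragged_names_record(self, tmp_path):
        fa = tmp_path / "a.fasta"
        fa.write_text(">a\nACGT\n>b\nACG\n")
        with pytest.raises(ValueError, match="'b'"):
            read_alignment(fa, {"a": "x", "b": "x"})

    def test_lowercase_uppercased(self, tmp_path):
        fa = tmp_path / "a.fasta"
        fa.write_text(">a\nacgt\n>b\nACGT\n")
        out = read_alignment(fa, {"a": "x", "b": "x"})
        assert out.records["a"] == "ACGT"

    def test_unmapped_id_rejected(self, tmp_path):
        fa = tmp_path / "a.fasta"
        fa.write_text(">a\nACGT\n>b\nACGT\n")
        with pytest.raises(ValueError, match="b"):
            read_alignment(fa, {"a": "x"})

    def test_illegal_characters_rejected(self, tmp_path):
        fa = tmp_path / "a.fasta"
        fa.write_text(">a\nAC!T\n")
        with pytest.raises(ValueError, match="'a'"):
            read_alignment(fa, {"a": "x"})


class TestK2P:
    def test_identical_zero(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form(self):
        # 100 sites, 2 transitions (A->G), 1 transversion (A->C):
        # K = -1/2 ln(0.95 * sqrt(0.98))
        s1 = "A" * 100
        s2 = "G" * 2 + "C" + "A" * 97
        expected = -0.5 * np.log(0.95 * np.sqrt(0.98))
        assert abs(k2p_distance(s1, s2) - expected) < 1e-12

    def test_symmetry(self):
        s1, s2 = "ACGTACGTAA", "ACGAACTTAA"
        assert k2p_distance(s1, s2) == k2p_distance(s2, s1)

    def test_pairwise_deletion(self):
        # positions with N or gap in either sequence are excluded, so only
        # sites 0-2 compare (one A/G transition among 3 sites)
        assert k2p_distance("ACGN-", "GCGTA") == pytest.approx(k2p_distance("ACG", "GCG"))

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            k2p_distance("NNNN", "ACGT")

    def test_saturated_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            k2p_distance("AAAA", "GGGG")  # P = 1

    @given(st.integers(0, 6), st.integers(0, 6), st.integers(60, 200))
    @settings(max_examples=60, deadline=None)
    def test_k2p_ge_p_distance(self, nts, ntv, length):
        # K2P corrects for multiple hits, so K >= p-distance on valid domain
        if nts + ntv >= length:
            return
        s1 = "A" * length
        s2 = "G" * nts + "C" * ntv + "A" * (length - nts - ntv)
        P, Q = nts / length, ntv / length
        if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
            return
        assert k2p_distance(s1, s2) >= p_distance(s1, s2) - 1e-12

    def test_matrix_symmetric_zero_diagonal(self):
        a = aln({"a": "ACGTAC", "b": "ACGAAC", "c": "TCGTAC"})
        m = k2p_matrix(a)
        assert np.allclose(m.to_numpy(), m.to_numpy().T)
        assert np.allclose(np.diag(m.to_numpy()), 0)


class TestGroupSummary:
    def test_single_pair_case(self):
        recs = {"a": "A" * 99 + "G", "b": "A" * 100}
        a = aln(recs, {"a": "g1", "b": "g2"})
        mat, _ = group_distance_summary(a, outgroup="zz")
        assert mat.loc["g1", "g2"] == pytest.approx(k2p_distance(recs["a"], recs["b"]))

    def test_within_group_clones_zero(self):
        a = aln(
            {"a": "ACGT", "b": "ACGT", "c": "ACGA"},
            {"a": "g1", "b": "g1", "c": "g2"},
        )
        mat, _ = group_distance_summary(a, outgroup="zz")
        assert mat.loc["g1", "g1"] == 0.0

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(4)
        ids = [f"s{i}" for i in range(8)]
        bases = "ACGT"
        recs = {}
        base = rng.integers(0, 4, 60)
        for i in ids:
            seq = base.copy()
            nmut = rng.integers(0, 4)
            pos = rng.choice(60, nmut, replace=False)
            seq[pos] = (seq[pos] + rng.integers(1, 4, nmut)) % 4
            recs[i] = "".join(bases[b] for b in seq)
        groups = {i: f"g{k % 3}" for k, i in enumerate(ids)}
        a = aln(recs, groups)
        mat, _ = group_distance_summary(a, outgroup="zz")
        # oracle: explicit double loop
        for g1, g2 in itertools.combinations(sorted(set(groups.values())), 2):
            vals = [
                k2p_distance(recs[i], recs[j])
                for i in ids if groups[i] == g1
                for j in ids if groups[j] == g2
            ]
            assert mat.loc[g1, g2] == pytest.approx(np.mean(vals))

    def test_summary_min_max(self):
        a = aln(
            {"a": "A" * 100, "b": "G" + "A" * 99, "c": "GG" + "A" * 98, "d": "GGGGG" + "A" * 95},
            {"a": "g1", "b": "g2", "c": "g3", "d": "tellensis"},
        )
        _, s = group_distance_summary(a)
        assert s["ingroup_min"] == pytest.approx(k2p_distance("A" * 100, "G" + "A" * 99))
        assert s["outgroup_max"] > s["outgroup_min"] > s["ingroup_max"]


class TestCollapseHaplotypes:
    def test_basic_counts(self):
        a = aln({"a": "AAA", "b": "AAA", "c": "AAT"})
        haps = collapse_haplotypes(a)
        assert [(h.sequence, h.count) for h in haps] == [("AAA", 2), ("AAT", 1)]
        assert sum(1 for h in haps if h.count == 1) == 1

    def test_gap_column_masked(self):
        a = aln({"a": "AA-", "b": "AAT"})
        haps = collapse_haplotypes(a)
        assert [(h.sequence, h.count) for h in haps] == [("AA", 2)]

    def test_order_invariance(self):
        recs = {"a": "ACGT", "b": "ACGA", "c": "ACGT", "d": "TCGA"}
        a1 = aln(dict(recs))
        a2 = aln(dict(reversed(list(recs.items()))))
        h1 = collapse_haplotypes(a1)
        h2 = collapse_haplotypes(a2)
        assert [(h.sequence, h.members) for h in h1] == [(h.sequence, h.members) for h in h2]

    def test_counts_conserve_sample_size(self):
        rng = np.random.default_rng(7)
        recs = {f"s{i}": "".join(rng.choice(list("ACGT"), 10)) for i in range(12)}
        a = aln(recs)
        haps = collapse_haplotypes(a)
        assert sum(h.count for h in haps) == 12
        all_members = [m for h in haps for m in h.members]
        assert sorted(all_members) == sorted(recs)

    def test_all_masked_rejected(self):
        a = aln({"a": "N-", "b": "AN"})
        with pytest.raises(ValueError, match="masked"):
            collapse_haplotypes(a)


def haps_of(seqs):
    return [Haplotype(s, (f"m{i}",)) for i, s in enumerate(seqs)]


class TestMedianJoining:
    def test_chain_no_medians(self):
        net = median_joining(haps_of(["000", "100", "110"]))
        assert net.median_nodes == []
        assert net.total_length() == 2
        assert sorted(net.graph.edges) == [("000", "100"), ("100", "110")]

    def test_star_infers_steiner_point(self):
        net = median_joining(haps_of(["100", "010", "001"]))
        assert net.median_nodes == ["000"]
        assert net.total_length() == 3
        assert net.graph.degree["000"] == 3

    def test_single_haplotype(self):
        net = median_joining([Haplotype("ACGT", ("a",))])
        assert net.graph.number_of_nodes() == 1
        assert net.graph.number_of_edges() == 0

    def test_connected_and_weights_are_hamming(self):
        net = median_joining(haps_of(["0000", "1100", "1010", "0011"]))
        import networkx as nx

        assert nx.is_connected(net.graph)
        for a, b, d in net.graph.edges(data="mutations"):
            assert d == hamming(a, b) >= 1

    def test_median_degree_at_least_three(self):
        for seqs in [["100", "010", "001"], ["10000", "01000", "00100", "10011", "01011", "00111"]]:
            net = median_joining(haps_of(seqs))
            for m in net.median_nodes:
                assert net.graph.degree[m] >= 3

    def test_input_order_invariance(self):
        seqs = ["0000", "1100", "1010", "0011", "1111"]
        n1 = median_joining(haps_of(seqs))
        n2 = median_joining(haps_of(list(reversed(seqs))))
        assert sorted(n1.graph.nodes) == sorted(n2.graph.nodes)
        assert sorted(map(tuple, map(sorted, n1.graph.edges))) == sorted(
            map(tuple, map(sorted, n2.graph.edges))
        )

    def test_msn_over_final_nodes_is_network(self):
        seqs = ["100", "010", "001", "111"]
        net = median_joining(haps_of(seqs))
        nodes = sorted(net.graph.nodes)
        edges = {(nodes[i], nodes[j]) for i, j, _ in _msn_edges(nodes, 0)}
        got = {tuple(sorted(e)) for e in net.graph.edges}
        assert {tuple(sorted(e)) for e in edges} == got

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_joining([])


class TestNetworkStats:
    def test_star_distances(self):
        centre = Haplotype("0000", tuple(f"c{i}" for i in range(5)))
        leaves = [
            Haplotype("1000", ("a",)), Haplotype("0100", ("b",)),
            Haplotype("0010", ("c",)), Haplotype("0001", ("d",)),
        ]
        net = median_joining([centre] + leaves)
        st = network_stats(net)
        assert st["modal_haplotype"] == "0000"
        for leaf in ("1000", "0100", "0010", "0001"):
            assert st["distance_from_modal"][leaf] == 1

    def test_chain_modal_and_distance(self):
        a = Haplotype("AA", ("x", "y", "z"))
        b = Haplotype("AT", ("w",))
        c = Haplotype("TT", ("v",))
        net = median_joining([a, b, c])
        st = network_stats(net)
        assert st["modal_haplotype"] == "AA"
        assert st["distance_from_modal"]["TT"] == 2
        assert st["n_singletons"] == 2

    def test_distances_match_floyd_warshall_oracle(self):
        seqs = ["0000", "1100", "1010", "0011", "1111", "0110"]
        net = median_joining(haps_of(seqs))
        st = network_stats(net)
        nodes = list(net.graph.nodes)
        edges = [(a, b, d) for a, b, d in net.graph.edges(data="mutations")]
        oracle = floyd_warshall(nodes, edges)
        modal = st["modal_haplotype"]
        for n, d in st["distance_from_modal"].items():
            assert d == oracle[(modal, n)]


class TestExports:
    def test_nexus_written(self, tmp_path):
        net = median_joining(haps_of(["100", "010", "001"]))
        out = tmp_path / "net.nex"
        write_nexus_network(net, out)
        text = out.read_text()
        assert text.startswith("#NEXUS")
        assert "BEGIN NETWORK;" in text
        assert "median_1" in text
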