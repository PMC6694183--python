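"""Coabundance networks, Markov clustering, enrichment, overlaps."""

from itertools import combinations
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rumiprox.abundance import AbundanceMatrix
from rumiprox.network import (CoabundanceNetwork, build_network, carry_forward,
                              covering_threshold, enrich, mcl_cluster,
                              overlap_sets, trait_gene_sets)
from rumiprox.reference import reference_gene_sets


def _matrix_from_corr(R, n_samples=200, seed=0):
    """Gaussian abundance-like matrix with (approximately) given gene-gene
    correlations, closed to compositional rows."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(R + 1e-9 * np.eye(len(R)))
    Z = rng.standard_normal((n_samples, len(R))) @ L.T
    raw = np.exp(0.2 * Z + 3)
    vals = pd.DataFrame(raw / raw.sum(1, keepdims=True),
                        columns=[f"K{j+1:05d}" for j in range(len(R))],
                        index=[f"a{i}" for i in range(n_samples)])
    return AbundanceMatrix(values=vals)


def _dense_mcl_oracle(A, inflation=2.0, pre_inflation=2.0, iters=300):
    """Minimal dense-matrix MCL, independent of the package implementation:
    no pruning, plain numpy loops, clusters from the limit matrix rows."""
    W = A.copy() ** pre_inflation
    np.fill_diagonal(W, 0.0)
    loops = W.max(axis=0)
    loops[loops == 0] = 1.0
    W = W + np.diag(loops)
    M = W / W.sum(axis=0, keepdims=True)
    for _ in range(iters):
        M = M @ M
        M = M**inflation
        M = M / M.sum(axis=0, keepdims=True)
        M[M < 1e-12] = 0.0
        M = M / M.sum(axis=0, keepdims=True)
    # connected components of the limit support
    g = nx.from_numpy_array((M + M.T) > 1e-6)
    labels = np.zeros(len(A), dtype=int)
    for cid, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            labels[node] = cid
    return labels


class TestCoveringThreshold:
    def test_hand_built_three_genes(self):
        R = pd.DataFrame([[1, .9, .5], [.9, 1, .2], [.5, .2, 1]],
                         index=list("abc"), columns=list("abc"))
        m = _matrix_from_corr(np.eye(3))
        assert covering_threshold(m, corr=R) == pytest.approx(0.5)

    def test_duplicated_gene_maxes_out(self):
        R = pd.DataFrame(np.ones((2, 2)), index=["a", "b"], columns=["a", "b"])
        m = _matrix_from_corr(np.eye(2))
        assert covering_threshold(m, corr=R) == pytest.approx(1.0)

    def test_grid_refinement(self):
        rng = np.random.default_rng(5)
        R = np.eye(6)
        for i, j in combinations(range(6), 2):
            R[i, j] = R[j, i] = rng.uniform(0.2, 0.9)
        Rdf = pd.DataFrame(R, index=list("abcdef"), columns=list("abcdef"))
        m = _matrix_from_corr(np.eye(6))
        coarse = covering_threshold(m, grid_step=0.05, corr=Rdf)
        fine = covering_threshold(m, grid_step=0.01, corr=Rdf)
        assert fine >= coarse
        assert fine - coarse < 0.05

    def test_covering_network_has_no_isolated_node(self, small_study):
        from rumiprox.abundance import filter_genes
        filt, _ = filter_genes(small_study.abundance)
        t = covering_threshold(filt)
        net = build_network(filt, t)
        assert not net.isolated
        one_up = build_network(filt, min(t + 0.01, 1.0))
        assert one_up.isolated

    def test_constant_gene_rejected(self):
        vals = pd.DataFrame({"K00001": [.5, .5, .5], "K00002": [.5, .5, .5]},
                            index=list("abc"))
        with pytest.raises(ValueError, match="constant"):
            covering_threshold(AbundanceMatrix(values=vals))


class TestBuildNetwork:
    def test_duplicated_genes_single_unit_edge(self, rng):
        x = rng.random(30)
        vals = pd.DataFrame({"K00001": x, "K00002": x, "K00003": rng.random(30)})
        vals.index = [f"a{i}" for i in range(30)]
        m = AbundanceMatrix(values=vals.div(vals.sum(1), axis=0) * 0 + vals)
        net = build_network(m, 0.99)
        assert net.graph.has_edge("K00001", "K00002")
        assert net.graph["K00001"]["K00002"]["r"] == pytest.approx(1.0)

    def test_negative_correlation_no_edge(self, rng):
        x = rng.standard_normal(30)
        vals = pd.DataFrame({"K00001": x - x.min() + .1,
                             "K00002": -x - (-x).min() + .1,
                             "K00003": rng.random(30)})
        vals.index = [f"a{i}" for i in range(30)]
        net = build_network(AbundanceMatrix(values=vals), 0.1)
        assert not net.graph.has_edge("K00001", "K00002")

    def test_block_density_contrast(self, small_study):
        """Planted blocks are denser inside than between at r = 0.8."""
        from rumiprox.abundance import filter_genes
        filt, _ = filter_genes(small_study.abundance)
        net = build_network(filt, 0.8)
        blocks = small_study.truth["blocks"]
        within = between = 0
        for u, v in net.graph.edges:
            if blocks[u] == blocks[v]:
                within += 1
            else:
                between += 1
        n = net.graph.number_of_nodes()
        sizes = pd.Series([blocks[g] for g in net.nodes]).value_counts()
        pairs_within = sum(s * (s - 1) // 2 for s in sizes)
        pairs_between = n * (n - 1) // 2 - pairs_within
        assert within / max(pairs_within, 1) > 10 * between / max(pairs_between, 1)


class TestMclCluster:
    def test_two_disjoint_cliques(self):
        g = nx.Graph()
        for base in (0, 4):
            for i, j in combinations(range(4), 2):
                g.add_edge(f"n{base+i}", f"n{base+j}", r=0.9)
        cl = mcl_cluster(CoabundanceNetwork(graph=g, threshold=0.5))
        assert sorted(cl.sizes) == [4, 4]
        first = {n for n in cl.assignment.index if cl.assignment[n] == 1}
        assert first in ({f"n{i}" for i in range(4)},
                         {f"n{i}" for i in range(4, 8)})

    def test_single_edge_single_cluster(self):
        g = nx.Graph()
        g.add_edge("a", "b", r=0.8)
        cl = mcl_cluster(CoabundanceNetwork(graph=g, threshold=0.5))
        assert cl.sizes.to_dict() == {1: 2}

    def test_matches_independent_reference(self):
        """30-node, 3-block weighted graph: partition identical to the
        independent dense MCL oracle (adjusted Rand index 1)."""
        from sklearn.metrics import adjusted_rand_score
        rng = np.random.default_rng(2)
        n = 30
        A = np.zeros((n, n))
        truth = np.repeat([0, 1, 2], 10)
        for i, j in combinations(range(n), 2):
            if truth[i] == truth[j] and rng.random() < 0.8:
                A[i, j] = A[j, i] = rng.uniform(0.7, 0.95)
            elif truth[i] != truth[j] and rng.random() < 0.05:
                A[i, j] = A[j, i] = rng.uniform(0.3, 0.5)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i, j in combinations(range(n), 2):
            if A[i, j] > 0:
                g.add_edge(i, j, r=A[i, j])
        cl = mcl_cluster(CoabundanceNetwork(graph=g, threshold=0.3))
        oracle = _dense_mcl_oracle(A)
        assert adjusted_rand_score(oracle, cl.assignment.to_numpy()) == pytest.approx(1.0)
        assert adjusted_rand_score(truth, cl.assignment.to_numpy()) == pytest.approx(1.0)

    def test_partition_and_size_ordering(self, small_study):
        from rumiprox.abundance import filter_genes
        filt, _ = filter_genes(small_study.abundance)
        net = build_network(filt, 0.8)
        cl = mcl_cluster(net)
        assert sorted(cl.assignment.index) == sorted(net.nodes)  # partition
        sizes = cl.sizes
        assert (sizes.index == np.arange(1, len(sizes) + 1)).all()
        assert (np.diff(sizes.to_numpy()) <= 0).all()

    def test_flow_matrix_column_stochastic(self):
        from rumiprox.network import _normalize_columns
        from scipy import sparse
        rng = np.random.default_rng(0)
        M = sparse.random(50, 50, density=0.2, random_state=1, format="csc")
        norm = _normalize_columns(M)
        sums = np.asarray(norm.sum(axis=0)).ravel()
        nonzero = np.asarray((M != 0).sum(axis=0)).ravel() > 0
        np.testing.assert_allclose(sums[nonzero], 1.0, atol=1e-9)


class TestCarryForward:
    def test_all_selected_in_one_cluster(self):
        g = nx.Graph()
        for i, j in combinations(range(4), 2):
            g.add_edge(f"n{i}", f"n{j}", r=0.9)
        g.add_edge("m1", "m2", r=0.9)
        cl = mcl_cluster(CoabundanceNetwork(graph=g, threshold=0.5))
        out = carry_forward(cl, {"n0"})
        assert set(out) == {f"n{i}" for i in range(4)}

    def test_no_selected_gene_error(self):
        g = nx.Graph()
        g.add_edge("a", "b", r=0.9)
        cl = mcl_cluster(CoabundanceNetwork(graph=g, threshold=0.5))
        with pytest.raises(ValueError, match="no selected gene"):
            carry_forward(cl, {"zzz"})

    def test_superset_of_in_network_selected(self, small_study):
        from rumiprox.abundance import filter_genes
        filt, _ = filter_genes(small_study.abundance)
        net = build_network(filt, 0.7)
        cl = mcl_cluster(net)
        selected = set(small_study.truth["signal_genes"]["FCR"])
        out = set(carry_forward(cl, selected))
        assert (selected & set(net.nodes)) <= out


class TestEnrich:
    @staticmethod
    def _exact_tail(N, K, n, k):
        return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / comb(N, n)

    def test_worked_example(self):
        assign = pd.Series([1] * 5 + [2] * 15,
                           index=[f"K{j:05d}" for j in range(20)])
        from rumiprox.network import Clustering
        cl = Clustering(assignment=assign, inflation=2, pre_inflation=2,
                        converged=True)
        genes = set(assign.index[:3]) | {assign.index[6]}  # k=3 in cluster 1, K=4
        table = enrich(cl, {"FCR": genes}, set(assign.index))
        row = table[(table.cluster == 1)].iloc[0]
        assert row["p"] == pytest.approx(self._exact_tail(20, 4, 5, 3))

    def test_exhaustive_small_universes(self):
        """Hypergeometric tail agrees with exact enumeration for all
        configurations with N <= 25."""
        from scipy.stats import hypergeom
        rng = np.random.default_rng(3)
        for _ in range(200):
            N = rng.integers(2, 26)
            K = rng.integers(0, N + 1)
            n = rng.integers(1, N + 1)
            k = rng.integers(0, min(K, n) + 1)
            p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
            assert p == pytest.approx(self._exact_tail(N, K, n, k), abs=1e-12)

    def test_zero_overlap_p_one(self):
        from rumiprox.network import Clustering
        assign = pd.Series([1] * 4 + [2] * 4,
                           index=[f"K{j:05d}" for j in range(8)])
        cl = Clustering(assignment=assign, inflation=2, pre_inflation=2,
                        converged=True)
        table = enrich(cl, {"X": set(assign.index[4:])}, set(assign.index))
        row = table[(table.cluster == 1) & (table.gene_set == "X")].iloc[0]
        assert row["overlap"] == 0 and row["p"] == 1.0

    def test_cluster_equals_universe(self):
        from rumiprox.network import Clustering
        assign = pd.Series([1] * 6, index=[f"K{j:05d}" for j in range(6)])
        cl = Clustering(assignment=assign, inflation=2, pre_inflation=2,
                        converged=True)
        table = enrich(cl, {"X": set(assign.index[:2])}, set(assign.index))
        assert table.iloc[0]["p"] == pytest.approx(1.0)


class TestOverlapSets:
    def test_reference_tables_shared_genes(self):
        """The published FCR and ADG selections share six genes, RFI and
        DFI share three."""
        sets = reference_gene_sets()
        report = overlap_sets(sets)
        assert report["pairwise"]["FCR∩ADG"] == sorted(
            ["K07561", "K01925", "K02437", "K03530", "K02600", "K02518"])
        assert report["pairwise"]["RFI∩DFI"] == sorted(
            ["K01709", "K00978", "K14113"])
        assert report["composite"]["FCR+ADG"] == report["pairwise"]["FCR∩ADG"]
        assert set(report["composite"]["FCR&ADG"]) == set(sets["FCR"]) | set(sets["ADG"])

    def test_disjoint_sets(self):
        report = overlap_sets({"FCR": ["K1", "K2"], "ADG": ["K3"]})
        assert report["pairwise"]["FCR∩ADG"] == []
        assert report["exclusive_counts"] == {"FCR": 2, "ADG": 1}

    def test_enrichment_set_construction(self):
        sets = trait_gene_sets({"FCR": ["a", "b"], "ADG": ["b", "c"],
                                "RFI": ["d"], "DFI": ["d", "e"]})
        assert sets["FCR&ADG"] == {"a", "b", "c"}
        assert sets["FCR+ADG"] == {"b"}
        assert sets["RFI&DFI"] == {"d", "e"}
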