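import math

import numpy as np
import networkx as nx
import pytest

import dasig
from dasig.de_network import (PPINetwork, bh_adjust, centrality,
                              compare_gene_lists_centrality,
                              differential_expression, first_shell,
                              load_edges, wilcoxon_rank_sum)
from dasig.matrix import ExpressionMatrix


def bh_oracle(p):
    """Literal step-up definition: sort, m*p/i, cumulative min from the top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        adj[idx] = running
    return adj


def betweenness_oracle(graph):
    """All-pairs BFS path counting (Brandes-free, brute force)."""
    nodes = list(graph.nodes)
    btw = dict.fromkeys(nodes, 0.0)
    for s in nodes:
        for t in nodes:
            if s >= t:
                continue
            try:
                paths = list(nx.all_shortest_paths(graph, s, t))
            except nx.NetworkXNoPath:
                continue
            for path in paths:
                for v in path[1:-1]:
                    btw[v] += 1.0 / len(paths)
    return btw


def two_group_matrix(rng, n_genes=50, n_per=25, shift=0.0, n_shifted=0):
    vals = rng.normal(size=(n_genes, 2 * n_per))
    vals[:n_shifted, n_per:] += shift
    labels = ["mild"] * n_per + ["severe"] * n_per
    X = ExpressionMatrix([f"G{i:03d}" for i in range(n_genes)],
                         [f"S{j}" for j in range(2 * n_per)], vals)
    return X, labels


class TestBhAdjust:
    def test_forced_values(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.42]), [0.42])

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(1)
        p = rng.random(100)
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_monotone_in_order_statistics_and_permutation_invariant(self):
        rng = np.random.default_rng(2)
        p = rng.random(40)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        perm = rng.permutation(40)
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestDifferentialExpression:
    def test_hand_case_unmoderated_pooled_t(self):
        # groups (1,2,3) vs (4,5,6): pooled variance s2 = (2+2)/4 = 1,
        # t = (5-2)/sqrt(1*(1/3+1/3)) = 3.674... (severe minus mild)
        X = ExpressionMatrix(["G"], [f"S{i}" for i in range(6)],
                             [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        res = differential_expression(X, ["mild"] * 3 + ["severe"] * 3,
                                      moderation=False)
        assert res.loc[0, "t_statistic"] == pytest.approx(3 / math.sqrt(2 / 3))
        assert res.loc[0, "log_fold_change"] == pytest.approx(3.0)

    def test_null_yields_almost_no_discoveries(self):
        counts = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, labels = two_group_matrix(rng, n_genes=1000, n_per=50)
            res = differential_expression(X, labels, alpha=0.1)
            counts.append(int(res["significant"].sum()))
        assert np.mean(counts) <= 5

    def test_power_on_planted_shift(self):
        recalls = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X, labels = two_group_matrix(rng, n_genes=500, n_per=40,
                                         shift=2.0, n_shifted=50)
            res = differential_expression(X, labels, alpha=0.1)
            hits = res.loc[res["significant"], "gene"]
            recalls.append(sum(g < "G050" for g in hits) / 50)
        assert np.mean(recalls) >= 0.8

    def test_moderation_limit_recovers_plain_t(self):
        rng = np.random.default_rng(3)
        X, labels = two_group_matrix(rng, n_genes=30, n_per=10)
        plain = differential_expression(X, labels, moderation=False)
        limit = differential_expression(X, labels, moderation=True,
                                        prior_df=1e-8)
        np.testing.assert_allclose(limit["t_statistic"], plain["t_statistic"],
                                   rtol=1e-6)

    def test_small_group_rejected(self):
        X = ExpressionMatrix(["G"], ["a", "b", "c"], [[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError):
            differential_expression(X, ["mild", "severe", "severe"])


class TestNetworkIo:
    def test_duplicate_and_self_edges_dropped(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\nB\tA\nA\tA\nB\tC\n")
        net = load_edges(path)
        assert sorted(net.edges) == [("A", "B"), ("B", "C")]
        assert net.n_duplicates_dropped == 1
        assert net.n_self_loops_dropped == 1

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("A\tB\nOOPS\n")
        with pytest.raises(ValueError, match="line 2"):
            load_edges(path)

    def test_generate_ppi_round_trip(self, tmp_path, small_cohort):
        cfg, _, _, structure = small_cohort
        net = dasig.generate_ppi(structure, cfg, seed=5)
        path = tmp_path / "ppi.tsv"
        net.write_tsv(path)
        loaded = load_edges(path)
        assert sorted(loaded.edges) == sorted(net.edges)


class TestFirstShell:
    def test_star_center_query_returns_whole_star(self):
        net = PPINetwork.from_edges("ABCDE", [("A", x) for x in "BCDE"])
        sub = first_shell(net, ["A"])
        assert sorted(sub.nodes) == list("ABCDE")

    def test_isolated_query_is_singleton(self):
        net = PPINetwork.from_edges(["A", "B", "C"], [("B", "C")])
        sub = first_shell(net, ["A"])
        assert sub.nodes == ["A"] and sub.edges == []

    def test_matches_neighbor_union_oracle(self):
        rng = np.random.default_rng(4)
        g = nx.gnp_random_graph(30, 0.1, seed=7)
        net = PPINetwork(nx.relabel_nodes(g, {i: f"N{i}" for i in g}))
        query = ["N0", "N5", "N11"]
        sub = first_shell(net, query)
        expected = set(query)
        for q in query:
            expected |= set(net.graph.neighbors(q))
        assert set(sub.nodes) == expected


class TestCentrality:
    def test_star_closed_form(self):
        n = 7
        net = PPINetwork.from_edges(
            [f"N{i}" for i in range(n)],
            [("N0", f"N{i}") for i in range(1, n)])
        cent = centrality(net)
        assert cent.loc["N0", "degree"] == n - 1
        assert cent.loc["N0", "betweenness"] == (n - 1) * (n - 2) / 2
        assert (cent.drop("N0")["betweenness"] == 0).all()

    def test_path_midpoint(self):
        net = PPINetwork.from_edges("ABC", [("A", "B"), ("B", "C")])
        assert centrality(net).loc["B", "betweenness"] == 1.0

    def test_random_graph_matches_bfs_oracle(self):
        g = nx.gnp_random_graph(15, 0.25, seed=11)
        net = PPINetwork(g)
        cent = centrality(net)
        oracle = betweenness_oracle(g)
        for node, expected in oracle.items():
            assert cent.loc[node, "betweenness"] == pytest.approx(expected)

    def test_tree_leaves_zero_and_degree_sum(self):
        g = nx.random_labeled_tree(20, seed=3)
        net = PPINetwork(g)
        cent = centrality(net)
        leaves = [n for n in g if g.degree(n) == 1]
        assert (cent.loc[leaves, "betweenness"] == 0).all()
        assert cent["degree"].sum() == 2 * g.number_of_edges()


class TestWilcoxon:
    def test_exact_small_case(self):
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_p_near_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 3, 4] * 5, [1, 2, 3, 4] * 5)
        assert p > 0.9

    def test_normal_approximation_matches_permutation_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.5, 1, 30)  # moderate shift: p in the well-calibrated
        b = rng.normal(0, 1, 30)    # range of the normal approximation
        w, p = wilcoxon_rank_sum(a, b)
        # Monte-Carlo permutation of the rank-sum statistic
        pooled = np.concatenate([a, b])
        from scipy.stats import rankdata
        ranks = rankdata(pooled)
        observed = ranks[:30].sum()
        n_resample = 200_000
        sums = np.empty(n_resample)
        chunk = 20_000
        for c in range(0, n_resample, chunk):
            idx = np.argsort(rng.random((chunk, 60)), axis=1)[:, :30]
            sums[c:c + chunk] = ranks[idx].sum(axis=1)
        centre = ranks.sum() * 30 / 60
        mc = np.mean(np.abs(sums - centre) >= abs(observed - centre) - 1e-9)
        assert p == pytest.approx(mc, rel=0.10)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestCompareCentrality:
    def test_planted_hubs_beat_background(self, small_cohort):
        cfg, _, _, structure = small_cohort
        wins = 0
        for seed in range(10):
            net = dasig.generate_ppi(structure, cfg, seed=seed)
            hubs = sorted(structure.all_module_gene_symbols())
            rng = np.random.default_rng(seed)
            background = list(rng.choice(
                [g for g in net.nodes if g not in set(hubs)], 90,
                replace=False))
            report = compare_gene_lists_centrality(net, hubs, background)
            wins += int(report["degree"]["p_greater"] < 0.05)
        assert wins >= 9

    def test_identical_lists_p_near_one(self, small_cohort):
        cfg, _, _, structure = small_cohort
        net = dasig.generate_ppi(structure, cfg, seed=0)
        genes = sorted(structure.all_module_gene_symbols())
        report = compare_gene_lists_centrality(net, genes, genes)
        assert report["degree"]["p_greater"] > 0.4

    def test_list_absent_from_network_errors(self, small_cohort):
        cfg, _, _, structure = small_cohort
        net = dasig.generate_ppi(structure, cfg, seed=0)
        with pytest.raises(ValueError):
            compare_gene_lists_centrality(net, ["NOPE1", "NOPE2"],
                                          sorted(net.nodes)[:5])
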