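"""Random walk with restart, permutation significance, CV AUC, categories."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ican.network_build import WeightedNetwork
from ican.prioritize import (
    alteration_categories,
    candidate_significance,
    compare_gene_properties,
    cv_auc,
    rwr,
)
from ican.synthetic import generate_network

from conftest import make_weighted, random_weighted_network


def linear_solve_oracle(network, seeds, r):
    """Direct steady state: p = r (I - (1-r) W)^-1 P0."""
    import networkx as nx

    nodes = sorted(network.graph.nodes)
    adj = nx.to_numpy_array(network.graph, nodelist=nodes, weight="weight")
    cols = adj.sum(axis=0)
    W = np.zeros_like(adj)
    nz = cols > 0
    W[:, nz] = adj[:, nz] / cols[nz]
    if (~nz).any():
        W[:, ~nz] = 1.0 / len(nodes)
    p0 = np.array([1.0 if n in seeds else 0.0 for n in nodes])
    p0 /= p0.sum()
    p = r * np.linalg.solve(np.eye(len(nodes)) - (1 - r) * W, p0)
    return nodes, p


class TestRWR:
    def test_single_node_seeded(self):
        import networkx as nx

        g = nx.Graph()
        g.add_node("A")
        res = rwr(WeightedNetwork(graph=g), {"A"})
        assert res.probabilities[0] == pytest.approx(1.0)

    def test_restart_one_returns_p0(self, path_network):
        res = rwr(path_network, {"A", "C"}, r=1.0)
        probs = dict(zip(res.nodes, res.probabilities))
        assert probs["A"] == probs["C"] == pytest.approx(0.5)
        assert probs["B"] == probs["D"] == 0.0

    def test_two_node_closed_form(self):
        net = make_weighted([("A", "B", 0.4)])
        res = rwr(net, {"A"}, r=0.7)
        nodes, expected = linear_solve_oracle(net, {"A"}, 0.7)
        got = dict(zip(res.nodes, res.probabilities))
        for n, e in zip(nodes, expected):
            assert got[n] == pytest.approx(e, abs=1e-10)

    def test_matches_linear_solve_on_random_graphs(self, rng):
        for _ in range(10):
            net = random_weighted_network(rng, n_nodes=60, p_edge=0.08)
            nodes = sorted(net.graph.nodes)
            seeds = set(rng.choice(nodes, size=5, replace=False))
            res = rwr(net, seeds)
            _, expected = linear_solve_oracle(net, seeds, 0.7)
            assert np.allclose(res.probabilities, expected, atol=1e-8)
            assert res.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_node_relabeling(self, rng):
        net = random_weighted_network(rng, n_nodes=40)
        nodes = sorted(net.graph.nodes)
        seeds = set(nodes[:4])
        res = rwr(net, seeds)
        import networkx as nx

        mapping = {n: f"Z{n}" for n in nodes}
        relabeled = WeightedNetwork(graph=nx.relabel_nodes(net.graph, mapping))
        res2 = rwr(relabeled, {mapping[s] for s in seeds})
        p1 = dict(zip(res.nodes, res.probabilities))
        p2 = dict(zip(res2.nodes, res2.probabilities))
        for n in nodes:
            assert p1[n] == pytest.approx(p2[mapping[n]], abs=1e-9)

    def test_seed_edge_weight_monotonicity(self):
        base = [("S", "A", 0.5), ("S", "B", 0.5), ("A", "B", 0.2)]
        low = rwr(make_weighted(base), {"S"})
        boosted = rwr(make_weighted([("S", "A", 0.9)] + base[1:]), {"S"})
        assert boosted.probability_of("A") >= low.probability_of("A")

    def test_no_seed_in_network_errors(self, path_network):
        with pytest.raises(ValueError, match="seed"):
            rwr(path_network, {"ZZZ"})

    def test_rank_ties_broken_by_symbol(self):
        net = make_weighted([("S", "A", 0.5), ("S", "B", 0.5)])
        df = rwr(net, {"S"}).to_frame()
        sub = df[df["gene"].isin(["A", "B"])]
        assert list(sub.sort_values("rank")["gene"]) == ["A", "B"]


class TestCandidateSignificance:
    def test_empirical_p_in_unit_interval_and_reproducible(self, rng):
        net = random_weighted_network(rng, n_nodes=60)
        nodes = sorted(net.graph.nodes)
        seeds = set(nodes[:5])
        t1 = candidate_significance(net, seeds, n_perm=100, rng=1)
        t2 = candidate_significance(net, seeds, n_perm=100, rng=1)
        assert t1.equals(t2)
        assert ((t1["empirical_p"] > 0) & (t1["empirical_p"] <= 1)).all()
        assert set(t1["gene"]).isdisjoint(seeds)

    def test_null_pvalues_near_uniform(self, rng):
        net, _ = generate_network(n_genes=120, module_size=0, rng=3)
        for a, b in net.graph.edges:
            net.graph[a][b]["weight"] = 1.0
        wnet = WeightedNetwork(graph=net.graph)
        pvals = []
        for rep in range(4):
            seeds = set(
                np.random.default_rng(rep).choice(sorted(net.graph.nodes), 8, replace=False)
            )
            t = candidate_significance(wnet, seeds, n_perm=150, rng=100 + rep)
            pvals.extend(t["empirical_p"])
        d = stats.kstest(pvals, "uniform").statistic
        assert d < 0.08

    def test_planted_module_neighbors_significant(self):
        # dense, strongly co-altered module (high edge weights) on a weakly
        # weighted scale-free background; non-seed members should stand out
        bg, truth = generate_network(
            n_genes=300, module_size=15, seeds_fraction=0.6, module_density=0.95, rng=5
        )
        members = truth.module_members
        for a, b in bg.graph.edges:
            inside = a in members and b in members
            bg.graph[a][b]["weight"] = 1.0 if inside else 0.05
        net = WeightedNetwork(graph=bg.graph)
        table = candidate_significance(net, truth.seed_genes, n_perm=3000, rng=9)
        non_seed_members = members - truth.seed_genes
        hits = table.set_index("gene").loc[sorted(non_seed_members), "adjusted_p"]
        assert (hits < 0.05).mean() >= 0.8

    def test_low_n_perm_warns(self, rng):
        net = random_weighted_network(rng, n_nodes=30)
        seeds = set(sorted(net.graph.nodes)[:3])
        with pytest.warns(UserWarning):
            candidate_significance(net, seeds, n_perm=50, rng=0)


class TestCVAuc:
    def test_perfect_separation(self):
        # held-out genes are exclusive neighbors of the seed hub
        edges = [("HUB", f"K{i}", 1.0) for i in range(10)]
        edges += [(f"X{i}", f"X{i+1}", 1.0) for i in range(6)]
        net = make_weighted(edges)
        known = {"HUB"} | {f"K{i}" for i in range(10)}
        res = cv_auc(net, known, folds=5, rng=0)
        assert res["mean_auc"] >= 0.99

    def test_random_known_set_auc_near_half(self, rng):
        aucs = []
        for rep in range(12):
            net = random_weighted_network(rng, n_nodes=80, p_edge=0.08)
            nodes = sorted(net.graph.nodes)
            known = set(rng.choice(nodes, size=15, replace=False))
            aucs.append(cv_auc(net, known, folds=5, rng=rep)["mean_auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.06

    def test_too_few_known_errors(self, path_network):
        with pytest.raises(ValueError):
            cv_auc(path_network, {"A"}, folds=5)


class TestGeneProperties:
    def test_identical_groups_p_one(self):
        stat, p = compare_gene_properties(np.ones(5), np.ones(7))
        assert p == 1.0

    def test_separated_groups_exact_p(self):
        stat, p = compare_gene_properties(np.array([1, 2, 3]), np.array([10, 11, 12]))
        assert stat == 0.0
        assert p == pytest.approx(0.1)

    def test_power_under_shift(self, rng):
        rejections = 0
        for _ in range(30):
            x = rng.normal(1.0, 1.0, size=50)
            y = rng.normal(0.0, 1.0, size=50)
            _, p = compare_gene_properties(x, y)
            rejections += p < 0.05
        assert rejections / 30 > 0.9


class TestAlterationCategories:
    @staticmethod
    def ranking(genes):
        return pd.DataFrame({"gene": genes, "rank": range(1, len(genes) + 1)})

    def test_triple_membership_counted_once(self):
        r = self.ranking([f"g{i}" for i in range(10)])
        out = alteration_categories(
            r, {"g0"}, {"g0"}, {"g0"}, top_fraction=1.0, bin_size=10
        )
        assert out.iloc[0]["GCD"] == 1
        assert out.iloc[0][["GE", "CN", "DM", "GC", "GD", "CD"]].sum() == 0

    def test_disjoint_sets_single_categories(self):
        r = self.ranking([f"g{i}" for i in range(9)])
        out = alteration_categories(
            r, {"g0", "g1"}, {"g2"}, {"g3", "g4", "g5"}, top_fraction=1.0, bin_size=9
        )
        row = out.iloc[0]
        assert (row["GE"], row["CN"], row["DM"]) == (2, 1, 3)
        assert row[["GC", "GD", "CD", "GCD"]].sum() == 0

    def test_counts_match_membership_oracle(self, rng):
        genes = [f"g{i}" for i in range(500)]
        r = self.ranking(genes)
        de = set(rng.choice(genes, 120, replace=False))
        cn = set(rng.choice(genes, 100, replace=False))
        dm = set(rng.choice(genes, 140, replace=False))
        out = alteration_categories(r, de, cn, dm, top_fraction=0.2, bin_size=40)
        top = genes[:100]
        # brute-force enumeration on the last (full top-fraction) bin
        last = out.iloc[-1]
        labels = {"GE": 0, "CN": 0, "DM": 0, "GC": 0, "GD": 0, "CD": 0, "GCD": 0}
        for g in top:
            key = (g in de, g in cn, g in dm)
            name = {
                (True, False, False): "GE",
                (False, True, False): "CN",
                (False, False, True): "DM",
                (True, True, False): "GC",
                (True, False, True): "GD",
                (False, True, True): "CD",
                (True, True, True): "GCD",
            }.get(key)
            if name:
                labels[name] += 1
        for name, count in labels.items():
            assert last[name] == count

    def test_bin_larger_than_list_gives_single_bin(self):
        r = self.ranking(["a", "b", "c"])
        out = alteration_categories(r, set(), set(), set(), top_fraction=1.0, bin_size=100)
        assert len(out) == 1
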