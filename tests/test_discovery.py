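"""Diffusion expansion, active-subnetwork annealing, signature combination."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from conftest import network_from_nx
from t2di.config import SimConfig
from t2di.discovery import (
    ActiveModuleScore,
    calibrate_score,
    combine_signatures,
    diamond_connectivity_p,
    diamond_run,
    gene_zscore,
    jactivemodules_run,
    recursive_search,
    subnetwork_score,
)
from t2di.network import Network, merge_networks
from t2di.synthetic import sample_groups, simulate_expression, simulate_interactome


def exact_hypergeom_tail(N, s, k, ks):
    """Independent oracle: direct combinatorial sum of the connectivity tail."""
    total = math.comb(N, k)
    return sum(math.comb(s, i) * math.comb(N - s, k - i) for i in range(ks, min(k, s) + 1)) / total


class TestConnectivityP:
    def test_hand_computed_example(self):
        assert diamond_connectivity_p(10, 3, 2, 2) == pytest.approx(3 / 45, rel=1e-12)

    def test_zero_links_full_tail(self):
        assert diamond_connectivity_p(50, 10, 5, 0) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(200):
            N = int(rng.integers(5, 31))
            s = int(rng.integers(1, N))
            k = int(rng.integers(1, N))
            ks = int(rng.integers(0, min(k, s) + 1))
            assert diamond_connectivity_p(N, s, k, ks) == pytest.approx(
                exact_hypergeom_tail(N, s, k, ks), rel=1e-9, abs=1e-12
            )

    def test_decreasing_in_ks(self):
        for N, s, k in [(20, 5, 8), (30, 10, 12), (15, 7, 7)]:
            ps = [diamond_connectivity_p(N, s, k, ks) for ks in range(min(k, s) + 1)]
            assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            diamond_connectivity_p(10, 3, 2, 3)
        with pytest.raises(ValueError):
            diamond_connectivity_p(10, 10, 2, 1)
        with pytest.raises(ValueError):
            diamond_connectivity_p(10, 3, 10, 1)


class TestDiamondRun:
    def test_hub_beats_peripheral_gene(self):
        # hub H adjacent to all three seeds and to X; X has no other links
        net = Network.from_edges([("H", "A"), ("H", "B"), ("H", "C"), ("H", "X")])
        out = diamond_run(net, {"A", "B", "C"}, n_iter=1)
        assert out[0].gene == "H" and out[0].ks == 3

    def test_seeds_covering_component_terminates_early(self):
        net = Network.from_edges([("A", "B"), ("C", "D")])
        out = diamond_run(net, {"A", "B"}, n_iter=10)
        assert out == []

    def test_absent_seeds_dropped_all_absent_is_error(self):
        net = Network.from_edges([("A", "B")])
        with pytest.raises(ValueError):
            diamond_run(net, {"ZZZ"})

    def test_insertion_order_invariance(self, rng):
        g = nx.gnp_random_graph(40, 0.12, seed=4)
        net1 = network_from_nx(g)
        net2 = Network()
        edges = list(g.edges)
        rng.shuffle(edges)
        for a, b in edges:
            net2.add_edge(f"N{a:04d}", f"N{b:04d}")
        seeds = {f"N{i:04d}" for i in (0, 3, 7)} & net1.nodes
        out1 = [d.gene for d in diamond_run(net1, seeds, n_iter=15)]
        out2 = [d.gene for d in diamond_run(net2, seeds, n_iter=15)]
        assert out1 == out2

    def test_recovers_planted_module_quickly(self):
        recovered = []
        for seed in range(5):
            cfg = SimConfig(seed=seed + 200)
            net, truth = simulate_interactome(cfg)
            out = diamond_run(net, truth.seed_genes, n_iter=40)
            nonseed = truth.module_genes - truth.seed_genes
            recovered.append(sum(1 for d in out if d.gene in nonseed) / len(nonseed))
        assert np.mean(recovered) >= 0.6


class TestZScores:
    def test_half_is_zero(self):
        assert gene_zscore(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_standard_quantile(self):
        assert gene_zscore(0.05) == pytest.approx(1.6449, abs=1e-4)

    def test_tiny_p_clamped(self):
        with pytest.warns(UserWarning, match="clamp"):
            z = gene_zscore(1e-300)
        assert z == pytest.approx(7.034, abs=1e-3)

    def test_subnetwork_score_examples(self):
        assert subnetwork_score([1.6449, 1.6449]) == pytest.approx(2.3262, abs=1e-4)
        assert subnetwork_score([0.0]) == 0.0


class TestCalibration:
    def test_uniform_p_gives_standard_moments(self, rng):
        # mu_k tracks sqrt(k) times the population mean z, whose sampling sd
        # is 1/sqrt(n_genes); 2000 genes keep it well inside +/-0.1
        g = nx.gnp_random_graph(2000, 0.005, seed=2)
        net = network_from_nx(g)
        gene_p = {n: float(p) for n, p in zip(sorted(net.nodes), rng.uniform(size=2000))}
        mu, sigma = calibrate_score(net, gene_p, k=10, n_samples=5000, seed=1)
        assert abs(mu) < 0.1
        assert 0.85 <= sigma <= 1.15

    def test_exact_matches_monte_carlo(self, rng):
        g = nx.gnp_random_graph(100, 0.05, seed=3)
        net = network_from_nx(g)
        gene_p = {n: float(p) for n, p in zip(sorted(net.nodes), rng.uniform(size=100))}
        mu_mc, sd_mc = calibrate_score(net, gene_p, k=8, n_samples=8000, seed=2)
        mu_ex, sd_ex = calibrate_score(net, gene_p, k=8, method="exact")
        assert mu_ex == pytest.approx(mu_mc, abs=0.05)
        assert sd_ex == pytest.approx(sd_mc, rel=0.05)


def enumerate_connected_subgraphs(graph: nx.Graph):
    """All connected induced subgraphs (as frozensets) of a small graph."""
    nodes = sorted(graph.nodes)
    for r in range(1, len(nodes) + 1):
        for combo in itertools.combinations(nodes, r):
            if nx.is_connected(graph.subgraph(combo)):
                yield frozenset(combo)


class TestAnnealing:
    def test_finds_global_optimum_on_path(self):
        g = nx.path_graph(10)
        net = network_from_nx(g)
        nodes = sorted(net.nodes)
        gene_p = {n: 0.99 for n in nodes}
        for n in nodes[4:7]:
            gene_p[n] = 1e-6
        modules = jactivemodules_run(net, gene_p, iterations=10_000, n_modules=1, seed=5)
        relabel = {f"N{i:04d}": i for i in range(10)}
        # brute-force oracle over all connected induced subgraphs
        z = {n: None for n in nodes}
        from t2di.discovery import _AnnealState
        state = _AnnealState(net, gene_p, 1)
        def s_a(genes):
            k = len(genes)
            zsum = sum(state.z[state.index[g]] for g in genes)
            return (zsum / np.sqrt(k) - state.mu_k[k]) / state.sigma_k[k]
        best = max(
            (frozenset(f"N{i:04d}" for i in sub) for sub in
             (set(c) for c in enumerate_connected_subgraphs(g))),
            key=s_a,
        )
        assert modules[0].genes == best
        assert modules[0].genes == frozenset(nodes[4:7])

    def test_all_equal_p_scores_near_zero(self):
        g = nx.gnp_random_graph(30, 0.15, seed=8)
        net = network_from_nx(g)
        gene_p = {n: 0.5 for n in net.nodes}
        for seed in range(5):
            modules = jactivemodules_run(net, gene_p, iterations=2000, seed=seed)
            assert all(abs(m.sA) < 3 for m in modules)

    def test_determinism(self):
        g = nx.gnp_random_graph(25, 0.2, seed=1)
        net = network_from_nx(g)
        rng = np.random.default_rng(55)
        gene_p = {n: float(p) for n, p in zip(sorted(net.nodes), rng.uniform(size=25))}
        a = jactivemodules_run(net, gene_p, iterations=3000, seed=9)
        b = jactivemodules_run(net, gene_p, iterations=3000, seed=9)
        assert [m.genes for m in a] == [m.genes for m in b]
        assert [m.sA for m in a] == [m.sA for m in b]

    def test_reported_score_internally_consistent(self):
        g = nx.gnp_random_graph(30, 0.15, seed=2)
        net = network_from_nx(g)
        rng = np.random.default_rng(7)
        gene_p = {n: float(p) for n, p in zip(sorted(net.nodes), rng.uniform(size=30))}
        from t2di.discovery import _AnnealState
        state = _AnnealState(net, gene_p, 5)
        for m in jactivemodules_run(net, gene_p, iterations=3000, seed=3):
            zA = sum(state.z[state.index[g]] for g in m.genes) / np.sqrt(m.k)
            sA = (zA - state.mu_k[m.k]) / state.sigma_k[m.k]
            assert m.zA == pytest.approx(zA, abs=1e-9)
            assert m.sA == pytest.approx(sA, abs=1e-9)

    def test_overlap_filter_limits_jaccard(self):
        g = nx.gnp_random_graph(40, 0.12, seed=6)
        net = network_from_nx(g)
        rng = np.random.default_rng(4)
        gene_p = {n: float(p) for n, p in zip(sorted(net.nodes), rng.uniform(size=40))}
        modules = jactivemodules_run(net, gene_p, iterations=4000, seed=2, overlap_threshold=0.1)
        for a, b in itertools.combinations(modules, 2):
            jac = len(a.genes & b.genes) / len(a.genes | b.genes)
            assert jac <= 0.1


class TestRecursiveSearch:
    def test_hsn2_contained_in_hsn1(self):
        g = nx.gnp_random_graph(30, 0.15, seed=12)
        net = network_from_nx(g)
        rng = np.random.default_rng(6)
        gene_p = {n: float(p) for n, p in zip(sorted(net.nodes), rng.uniform(size=30))}
        hsn1, hsn2 = recursive_search(net, gene_p, seed=1, iterations=3000)
        u1 = set().union(*(m.genes for m in hsn1)) if hsn1 else set()
        u2 = set().union(*(m.genes for m in hsn2)) if hsn2 else set()
        assert u2 <= u1

    def test_empty_gene_p_gives_empty_results(self):
        net = Network.from_edges([("A", "B")])
        hsn1, hsn2 = recursive_search(net, {}, seed=1, iterations=100)
        assert hsn1 == [] and hsn2 == []


class TestCombineSignatures:
    def test_inclusion_exclusion_counts(self):
        diamond = [f"D{i}" for i in range(19)] + [f"C{i}" for i in range(20)]
        hsn2 = {f"J{i}" for i in range(381)} | {f"C{i}" for i in range(20)}
        deg = set(diamond) | hsn2
        sig = combine_signatures(diamond, hsn2, deg)
        counts = sig.counts()
        assert counts["diamond"] == 39
        assert counts["jactivemodules"] == 401
        assert counts["both"] == 20
        assert counts["total"] == 39 + 401 - 20 == 420

    def test_empty_deg_empty_signatures(self):
        assert combine_signatures(["A"], {"B"}, set()).genes == set()

    def test_single_gene_all_methods(self):
        sig = combine_signatures(["G"], {"G"}, {"G"})
        assert sig.provenance == {"G": "both"}
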