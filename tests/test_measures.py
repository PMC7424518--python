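"""Network measures: degrees, strengths, distributions, fits, paths, centralities."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import optimize, special

from chronnet import (
    BuildConfig,
    build_chronnet,
    centrality,
    degree_distribution,
    degrees,
    edge_density,
    fit_discrete_powerlaw,
    fit_lognormal,
    path_stats,
    prune,
    strength_distribution,
    strengths,
    summarize,
    to_undirected,
    transitivity,
)

from conftest import random_cell_sequence


def wgraph(edges):
    g = nx.Graph()
    g.add_weighted_edges_from(edges)
    return g


class TestDegreesStrengths:
    def test_triangle_unit_weights(self):
        g = wgraph([(0, 1, 1), (1, 2, 1), (0, 2, 1)])
        assert degrees(g) == {0: 2, 1: 2, 2: 2}
        assert strengths(g) == {0: 2, 1: 2, 2: 2}

    def test_weighted_path(self):
        g = wgraph([(0, 1, 3), (1, 2, 1)])
        assert degrees(g)[1] == 2
        assert strengths(g)[1] == 4

    def test_self_loop_excluded_from_degree_included_in_strength(self):
        g = wgraph([(0, 1, 2), (0, 0, 5)])
        assert degrees(g)[0] == 1
        assert strengths(g)[0] == 7
        assert strengths(g, include_self_loops=False)[0] == 2

    def test_strengths_equal_weight_matrix_row_sums(self, random_undirected_chronnet):
        g = random_undirected_chronnet
        nodes = sorted(g.nodes)
        w = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
        # networkx puts the self-loop weight once on the diagonal; row sums
        # then match the strength definition sum_j w_ij directly
        row_sums = w.sum(axis=1)
        s = strengths(g)
        np.testing.assert_allclose([s[n] for n in nodes], row_sums)

    def test_handshake_identities(self, random_undirected_chronnet):
        g = random_undirected_chronnet
        no_loop_edges = [(u, v) for u, v in g.edges if u != v]
        assert sum(degrees(g).values()) == 2 * len(no_loop_edges)
        off = sum(w for u, v, w in g.edges(data="weight") if u != v)
        loops = sum(w for u, v, w in g.edges(data="weight") if u == v)
        assert sum(strengths(g).values()) == 2 * off + loops

    def test_directed_input_aggregated(self):
        net = build_chronnet([0, 1, 0], [1, 2, 3])
        assert strengths(net) == strengths(to_undirected(net))


class TestDistributions:
    def test_star_degree_distribution(self):
        star = wgraph([(0, i, 1) for i in range(1, 5)])
        k, p = degree_distribution(star)
        np.testing.assert_array_equal(k, [1, 4])
        np.testing.assert_allclose(p, [4 / 5, 1 / 5])

    def test_fractions_sum_to_one(self, random_undirected_chronnet):
        for dist in (degree_distribution, strength_distribution):
            _, p = dist(random_undirected_chronnet)
            assert p.sum() == pytest.approx(1.0)


def sample_discrete_powerlaw(gamma, n, rng, kmax=10**6):
    """Exact inverse-CDF sampler for P(k) ~ k^-gamma on 1..kmax (oracle)."""
    k = np.arange(1, kmax + 1, dtype=float)
    pmf = k**-gamma
    pmf /= pmf.sum()
    return np.searchsorted(np.cumsum(pmf), rng.random(n)) + 1


def mle_gamma_fixed_cutoff(values, k_min=1):
    """Independent MLE for the discrete power-law exponent at a fixed cutoff."""
    vals = np.asarray(values, dtype=float)
    vals = vals[vals >= k_min]
    slog = np.sum(np.log(vals))

    def nll(g):
        return len(vals) * np.log(special.zeta(g, k_min)) + g * slog

    return optimize.minimize_scalar(nll, bounds=(1.01, 20.0), method="bounded").x


class TestPowerLawFit:
    @pytest.mark.parametrize("gamma,tol", [(2.5, 0.15), (4.3, 0.2)])
    def test_recovers_generating_exponent(self, gamma, tol):
        hits = 0
        for seed in (1, 2, 3):
            x = sample_discrete_powerlaw(gamma, 10_000, np.random.default_rng(seed))
            fit = fit_discrete_powerlaw(x)
            if abs(fit.gamma - gamma) <= tol:
                hits += 1
        assert hits >= 2

    def test_agrees_with_independent_mle_at_fixed_cutoff(self):
        x = sample_discrete_powerlaw(3.0, 5_000, np.random.default_rng(7))
        fit = fit_discrete_powerlaw(x, k_min=1)
        assert fit.gamma == pytest.approx(mle_gamma_fixed_cutoff(x, 1), abs=0.02)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            fit_discrete_powerlaw([5, 5, 5, 5])


class TestLogNormalFit:
    def test_recovers_parameters(self):
        x = np.random.default_rng(1).lognormal(7.2, 1.8, 10_000)
        fit = fit_lognormal(x)
        assert fit.mu == pytest.approx(7.2, abs=0.05)
        assert fit.sigma == pytest.approx(1.8, abs=0.05)

    def test_scaling_by_e_shifts_mu_only(self):
        x = np.random.default_rng(2).lognormal(1.0, 0.5, 2_000)
        a, b = fit_lognormal(x), fit_lognormal(np.e * x)
        assert b.mu - a.mu == pytest.approx(1.0, abs=1e-9)
        assert b.sigma == pytest.approx(a.sigma, abs=1e-9)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            fit_lognormal([4.0])


def floyd_warshall_oracle(g, weight=None):
    """Exhaustive all-pairs shortest paths (dense O(n^3)); independent of networkx."""
    nodes = sorted(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for u, v, data in g.edges(data=True):
        if u == v:
            continue
        w = 1.0 if weight is None else 1.0 / data["weight"]
        i, j = idx[u], idx[v]
        d[i, j] = d[j, i] = min(d[i, j], w)
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return nodes, d


class TestPathsAndCentrality:
    def test_path_graph_hand_values(self):
        g = wgraph([(0, 1, 1), (1, 2, 1)])
        stats = path_stats(g)
        assert stats["average_path_length"] == pytest.approx(4 / 3)
        assert stats["diameter"] == 2
        clo = centrality(g, "closeness")
        assert clo[1] == pytest.approx(1 / 2)
        assert clo[0] == pytest.approx(1 / 3)

    def test_complete_graph_mean_path_one(self):
        g = wgraph([(u, v, 1) for u, v in itertools.combinations(range(6), 2)])
        assert path_stats(g)["average_path_length"] == pytest.approx(1.0)

    def test_star_center_dominates(self):
        star = wgraph([(0, i, 1) for i in range(1, 5)])
        deg = centrality(star, "degree")
        btw = centrality(star, "betweenness")
        assert max(deg, key=deg.get) == 0
        assert btw[0] == pytest.approx(6)  # all 6 leaf pairs route through it
        assert all(btw[i] == 0 for i in range(1, 5))

    def test_bridge_between_communities_maximizes_betweenness(self):
        g = wgraph([(u, v, 1) for u, v in itertools.combinations(range(4), 2)])
        g.add_weighted_edges_from(
            [(u, v, 1) for u, v in itertools.combinations(range(5, 9), 2)]
        )
        g.add_weighted_edges_from([(3, 4, 1), (4, 5, 1)])  # node 4 bridges
        btw = centrality(g, "betweenness")
        assert max(btw, key=btw.get) == 4

    def test_weighted_closeness_prefers_strong_links(self):
        # strong link = short temporal distance 1/w
        g = wgraph([(0, 1, 10), (1, 2, 1)])
        clo = centrality(g, "closeness", use_weights=True)
        assert clo[0] > clo[2]

    def test_path_and_centrality_match_exhaustive_oracle(self, rng):
        for _ in range(3):
            cells, times = random_cell_sequence(rng, 120, 25)
            g = to_undirected(build_chronnet(cells, times))
            for weighted in (False, True):
                nodes, d = floyd_warshall_oracle(g, weight="weight" if weighted else None)
                finite = d[np.isfinite(d) & (d > 0)]
                assert nx.is_connected(g)  # oracle comparison assumes one component
                stats = path_stats(g, use_weights=weighted)
                clo = centrality(g, "closeness", use_weights=weighted)
                for i, node in enumerate(nodes):
                    row = d[i][np.isfinite(d[i])]
                    if row.sum() > 0:
                        assert clo[node] == pytest.approx(1.0 / row.sum())
                if not weighted:
                    assert stats["average_path_length"] == pytest.approx(finite.mean())
                    assert stats["diameter"] == pytest.approx(finite.max())

    def test_closeness_scored_per_component(self):
        g = wgraph([(0, 1, 1), (2, 3, 1)])
        clo = centrality(g, "closeness")
        assert clo == {0: 1.0, 1: 1.0, 2: 1.0, 3: 1.0}

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            path_stats(nx.Graph())


def triad_census_transitivity(g):
    """3 * triangles / connected triples by brute-force enumeration."""
    nodes = [n for n in g.nodes]
    triangles = triples = 0
    for trio in itertools.combinations(nodes, 3):
        for center in trio:
            a, b = [n for n in trio if n != center]
            if g.has_edge(center, a) and g.has_edge(center, b):
                triples += 1
                if g.has_edge(a, b):
                    triangles += 1
    return triangles / triples if triples else 0.0


class TestTransitivityDensity:
    def test_triangle_and_path(self):
        assert transitivity(wgraph([(0, 1, 1), (1, 2, 1), (0, 2, 1)])) == 1.0
        assert transitivity(wgraph([(0, 1, 1), (1, 2, 1)])) == 0.0

    def test_matches_triad_census_oracle(self, random_undirected_chronnet):
        g = random_undirected_chronnet
        assert transitivity(g) == pytest.approx(triad_census_transitivity(g))

    def test_density_extremes_and_count(self, rng):
        k4 = wgraph([(u, v, 1) for u, v in itertools.combinations(range(4), 2)])
        assert edge_density(k4) == 1.0
        empty = nx.Graph()
        empty.add_nodes_from(range(4))
        assert edge_density(empty) == 0.0
        cells, times = random_cell_sequence(rng, 200, 15)
        g = to_undirected(build_chronnet(cells, times))
        m = sum(1 for u, v in g.edges if u != v)
        n = g.number_of_nodes()
        assert edge_density(g) == pytest.approx(m / (n * (n - 1) / 2))
        with pytest.raises(ValueError):
            edge_density(wgraph([]))

    def test_pruning_monotone_in_density_and_degree(self, random_undirected_chronnet):
        g = random_undirected_chronnet
        last_density = edge_density(g)
        last_deg = degrees(g)
        for tau in (1, 2, 4, 8):
            p = prune(g, tau)
            d = edge_density(p)
            assert d <= last_density + 1e-12
            deg = degrees(p)
            assert all(deg[n] <= last_deg[n] for n in deg)
            last_density, last_deg = d, deg


def test_summarize_is_json_serializable(random_undirected_chronnet):
    import json

    out = summarize(random_undirected_chronnet, fit_tails=True)
    json.dumps(out)
    assert out["n_nodes"] == random_undirected_chronnet.number_of_nodes()
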