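"""Degree-exponent estimation, subgraph summaries, and the resampling null."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.special import zeta

from txcontext.network import (
    betweenness_and_density,
    compare_to_null,
    fit_degree_exponent,
    induced_subgraph,
    random_null,
    read_edge_list,
    simplify,
    summarize_network,
    write_edge_list,
)
from txcontext.synthetic import simulate_network


# ---------------------------------------------------------------- subgraphs
def test_induced_subgraph_cases():
    tri = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
    sub = induced_subgraph(tri, {"a", "b"})
    assert set(sub.edges) == {("a", "b")}
    assert induced_subgraph(tri, {"x"}).number_of_nodes() == 0
    assert set(induced_subgraph(tri, {"a", "b", "c"}).edges) == set(tri.edges)


def test_simplify_removes_loops_and_is_idempotent():
    g = nx.MultiGraph()
    g.add_edges_from([("a", "a"), ("a", "b"), ("a", "b"), ("b", "c")])
    s = simplify(g)
    assert set(s.edges) == {("a", "b"), ("b", "c")}
    s2 = simplify(s)
    assert set(s2.edges) == set(s.edges) and set(s2.nodes) == set(s.nodes)


# ---------------------------------------------------------- exponent fitting
def _grid_oracle(degrees, x_min=1):
    """Brute-force maximizer of the discrete power-law log-likelihood."""
    d = np.array([x for x in degrees if x >= x_min], float)
    grid = np.arange(1.05, 8.0, 0.001)
    ll = [-len(d) * np.log(zeta(g, x_min)) - g * np.log(d).sum() for g in grid]
    return grid[int(np.argmax(ll))]


def test_mle_agrees_with_likelihood_grid():
    rng = np.random.default_rng(0)
    for gamma in (2.2, 3.0):
        deg = np.clip(rng.zipf(gamma, 1500), 1, 60)
        assert fit_degree_exponent(deg.tolist()) == pytest.approx(
            _grid_oracle(deg), abs=0.01
        )


def test_exponent_recovery_on_configuration_model():
    g, _ = simulate_network(n_nodes=2000, gamma_target=2.7, seed=3)
    gamma_hat = fit_degree_exponent(g)
    assert abs(gamma_hat - 2.7) <= 0.15


def test_degenerate_degrees_capped_with_warning():
    with pytest.warns(UserWarning, match="capped"):
        assert fit_degree_exponent([1] * 50) == 8.0


def test_too_few_nonzero_degrees_error():
    with pytest.raises(ValueError, match=">= 10"):
        fit_degree_exponent([0] * 20 + [3, 2])


def test_alternative_estimators_run():
    rng = np.random.default_rng(1)
    deg = np.clip(rng.zipf(2.5, 500), 1, 40).tolist()
    assert fit_degree_exponent(deg, method="loglog") > 1
    assert fit_degree_exponent(deg, x_min=6, method="approx") > 1
    with pytest.raises(ValueError, match="unknown method"):
        fit_degree_exponent(deg, method="nope")


# ------------------------------------------------- betweenness and density
def test_betweenness_closed_forms():
    k4 = nx.complete_graph(4)
    mb, dens = betweenness_and_density(k4)
    assert mb == 0.0 and dens == 1.0

    star = nx.star_graph(5)  # center + 5 leaves
    mb, dens = betweenness_and_density(star)
    # center carries all 10 leaf pairs; leaves carry none
    assert mb == pytest.approx(10 / 6)
    assert dens == pytest.approx(5 / 15)

    path = nx.path_graph(3)
    mb, dens = betweenness_and_density(path)
    assert mb == pytest.approx(1 / 3)
    assert dens == pytest.approx(2 / 3)


def _brute_betweenness(g):
    """All-pairs shortest-path enumeration, feasible for <= 8 nodes."""
    nodes = list(g.nodes)
    bc = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(v in p for p in paths)
            bc[v] += through / len(paths)
    return bc


def test_betweenness_matches_brute_force_on_small_graphs():
    rng = np.random.default_rng(2)
    for _ in range(25):
        n = int(rng.integers(3, 9))
        g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
        expected = _brute_betweenness(g)
        got = nx.betweenness_centrality(g, normalized=False)
        for v in g.nodes:
            assert got[v] == pytest.approx(expected[v], abs=1e-9)


# ------------------------------------------------------------ null sampling
@pytest.fixture(scope="module")
def net():
    g, _ = simulate_network(n_nodes=300, gamma_target=2.7, seed=5)
    return g


def test_null_with_full_pool_is_constant(net):
    pool = sorted(net.nodes)
    null = random_null(net, k=len(pool), n_replicates=3, candidate_pool=pool,
                       seed=1, with_betweenness=False)
    assert null.sd["gamma"] == 0.0
    assert null.sd["edge_density"] == 0.0


def test_null_is_bit_reproducible(net):
    pool = sorted(net.nodes)
    kw = dict(k=80, n_replicates=10, candidate_pool=pool, seed=42, with_betweenness=False)
    a = random_null(net, **kw)
    b = random_null(net, **kw)
    assert a.mean == b.mean and a.sd == b.sd
    assert [r.degree_histogram for r in a.replicates] == [
        r.degree_histogram for r in b.replicates
    ]


def test_null_rejects_oversized_sample(net):
    with pytest.raises(ValueError, match="exceeds"):
        random_null(net, k=1000, n_replicates=3, candidate_pool=sorted(net.nodes), seed=0)


def test_compare_to_null_examples(net):
    pool = sorted(net.nodes)
    null = random_null(net, k=60, n_replicates=99, candidate_pool=pool, seed=7,
                       with_betweenness=False)
    # observed equal to the null mean: p ~ 1, z = 0
    obs = summarize_network(
        induced_subgraph(net, pool[:60]), with_betweenness=False
    )
    fake = type(obs)(
        n_nodes=obs.n_nodes, n_edges=obs.n_edges, degree_histogram=obs.degree_histogram,
        gamma=null.mean["gamma"], mean_betweenness=None,
        edge_density=null.mean["edge_density"],
    )
    out = compare_to_null(fake, null)
    assert out["gamma"]["z_score"] == pytest.approx(0.0)
    assert out["gamma"]["empirical_p"] > 0.9
    # observed beyond every replicate with n = 99: add-one p = 1/100... but
    # two-sided extremes are counted against |obs - mean|
    extreme = type(obs)(
        n_nodes=obs.n_nodes, n_edges=obs.n_edges, degree_histogram=obs.degree_histogram,
        gamma=99.0, mean_betweenness=None, edge_density=1.0,
    )
    out = compare_to_null(extreme, null)
    n_valid = sum(r.gamma is not None for r in null.replicates)
    assert out["gamma"]["empirical_p"] == pytest.approx(1 / (n_valid + 1))
    assert out["edge_density"]["empirical_p"] == pytest.approx(1 / 100)


def test_degree_biased_sets_flatten_the_exponent():
    """Hub-biased gene sets have a smaller fitted exponent than random sets
    of the same size (the direction of the published contrast)."""
    wins = 0
    reps = 10
    for seed in range(reps):
        labels = [f"g{i:04d}" for i in range(600)]
        hubs = labels[:60]
        g, _ = simulate_network(
            n_nodes=600, gamma_target=2.7, seed=seed, node_labels=labels, hub_genes=hubs
        )
        obs = summarize_network(induced_subgraph(g, hubs), with_betweenness=False)
        null = random_null(g, k=60, n_replicates=30, candidate_pool=labels,
                           seed=seed, with_betweenness=False)
        if obs.gamma is not None and "gamma" in null.mean and obs.gamma < null.mean["gamma"]:
            wins += 1
    assert wins >= 0.8 * reps


# ------------------------------------------------------------------- I/O
def test_edge_list_round_trip(tmp_path, net):
    p = tmp_path / "net.tsv"
    write_edge_list(net, p)
    back = read_edge_list(p)
    assert set(map(frozenset, back.edges)) == set(map(frozenset, net.edges))


def test_edge_list_rejects_single_column(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("a\n")
    with pytest.raises(ValueError, match="2 columns"):
        read_edge_list(p)
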