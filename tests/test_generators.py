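"""Simulators: seed constructors, growth mechanisms, reproducibility."""

import math

import networkx as nx
import numpy as np
import pytest

from netresample.generators import (
    ModelSpec,
    SeedSpec,
    generate,
    generate_adjacency,
    seed_complete,
    seed_inverse_geometric,
    seed_two_clique_composite,
    triangle_closure_probability,
)


def spec_er(n, p, k=5):
    return ModelSpec("er_growth", n=n, seed=SeedSpec("complete", k=k), params={"p": p})


def spec_dmc(n, q_mod, q_con, k=5):
    return ModelSpec(
        "dmc", n=n, seed=SeedSpec("complete", k=k), params={"q_mod": q_mod, "q_con": q_con}
    )


def spec_dmr(n, q_del, q_new, k=5, remove_singletons=False):
    return ModelSpec(
        "dmr",
        n=n,
        seed=SeedSpec("complete", k=k),
        params={"q_del": q_del, "q_new": q_new},
        remove_singletons=remove_singletons,
    )


def spec_tc(n, m, p0=0.3, p1=0.1, p_delta=0.05):
    return ModelSpec(
        "triangle_closure", n=n, m=m, params={"p0": p0, "p1": p1, "p_delta": p_delta}
    )


# ---------------------------------------------------------------------------
# seeds


def test_seed_complete():
    assert seed_complete(5).number_of_edges() == 10
    g1 = seed_complete(1)
    assert g1.number_of_nodes() == 1 and g1.number_of_edges() == 0
    assert nx.utils.graphs_equal(seed_complete(3), nx.complete_graph(3))
    with pytest.raises(ValueError):
        seed_complete(0)


def test_seed_two_clique_structure(rng):
    g = seed_two_clique_composite(rng)
    assert g.number_of_nodes() == 50
    # K7 and K10 are intact
    assert all(g.has_edge(i, j) for i in range(7) for j in range(i + 1, 7))
    assert all(g.has_edge(i, j) for i in range(7, 17) for j in range(i + 1, 17))
    # the 33 extra nodes are pendants anchored inside the cliques
    for leaf in range(17, 50):
        nbrs = list(g.neighbors(leaf))
        assert len(nbrs) == 1 and nbrs[0] < 17


def test_seed_two_clique_mean_edges(rng):
    # E[m] = C(7,2) + C(10,2) + 70 * 0.67 + 33 = 145.9
    draws = 400
    counts = [seed_two_clique_composite(rng).number_of_edges() for _ in range(draws)]
    sd = math.sqrt(70 * 0.67 * 0.33)
    assert np.mean(counts) == pytest.approx(145.9, abs=3 * sd / math.sqrt(draws))


def test_seed_inverse_geometric(rng):
    # R = 0: all distinct standard-normal points are > 0 apart -> complete
    g = seed_inverse_geometric(10, 2, 0.0, rng)
    assert g.number_of_edges() == 45
    # per-pair edge probability: ||Delta||^2 ~ Exp(mean 4), P(>R^2) = exp(-R^2/4)
    dens = []
    for _ in range(200):
        g = seed_inverse_geometric(30, 2, 1.5, rng)
        dens.append(g.number_of_edges() / math.comb(30, 2))
    assert np.mean(dens) == pytest.approx(math.exp(-2.25 / 4), abs=0.02)
    # inverted convention gives the complementary probability
    g_in = seed_inverse_geometric(200, 2, 1.5, rng, connect_within=True)
    assert g_in.number_of_edges() / math.comb(200, 2) == pytest.approx(
        1 - math.exp(-2.25 / 4), abs=0.05
    )


# ---------------------------------------------------------------------------
# ER growth


def test_er_growth_deterministic_limits():
    k6 = generate(ModelSpec("er_growth", n=6, seed=SeedSpec("complete", k=1), params={"p": 1.0}), 0)
    assert nx.utils.graphs_equal(k6, nx.complete_graph(6))
    g = generate(spec_er(100, 0.0), 0)
    assert g.number_of_nodes() == 100 and g.number_of_edges() == 10


def test_er_growth_mean_edges(rng):
    n, p, draws = 100, 0.1, 300
    expected = 10 + (math.comb(n, 2) - 10) * p
    counts = [generate_adjacency(spec_er(n, p), rng).sum() / 2 for _ in range(draws)]
    sd = math.sqrt((math.comb(n, 2) - 10) * p * (1 - p))
    assert np.mean(counts) == pytest.approx(expected, abs=3 * sd / math.sqrt(draws))


def test_er_growth_seed_too_large():
    with pytest.raises(ValueError, match="smaller than seed"):
        spec_er(3, 0.5, k=5)


# ---------------------------------------------------------------------------
# DMC


def test_dmc_complete_preserved():
    g = generate(spec_dmc(10, 0.0, 1.0, k=3), 7)
    assert nx.utils.graphs_equal(g, nx.complete_graph(10))


@pytest.mark.parametrize("seed", range(5))
def test_dmc_full_modification_conserves_edges_each_step(seed):
    from netresample.generators import generate_dmc

    trace: list[int] = []
    g = generate_dmc(spec_dmc(60, 1.0, 0.0, k=6), seed, edge_trace=trace)
    assert g.number_of_nodes() == 60
    assert trace == [15] * 55  # seed m plus one entry per each of 54 steps


def test_dmc_zero_steps_returns_seed():
    g = generate(spec_dmc(5, 0.5, 0.5, k=5), 0)
    assert nx.utils.graphs_equal(g, nx.complete_graph(5))


# ---------------------------------------------------------------------------
# DMR


def test_dmr_pure_duplication_copies_neighborhood(rng):
    base = nx.gnp_random_graph(8, 0.4, seed=3)
    spec = ModelSpec(
        "dmr", n=9, seed=SeedSpec("explicit", graph=base), params={"q_del": 0.0, "q_new": 0.0}
    )
    g = generate(spec, rng)
    new_nbrs = set(g.neighbors(8))
    assert any(new_nbrs == set(base.neighbors(u)) for u in base.nodes)


def test_dmr_full_deletion_isolates_new_nodes():
    g = generate(spec_dmr(50, 1.0, 0.0), 5)
    assert g.number_of_nodes() == 50
    assert g.number_of_edges() == 10
    assert sum(1 for v in g if g.degree(v) == 0) == 45


def test_dmr_nonterminating_configuration_rejected():
    with pytest.raises(RuntimeError, match="singleton"):
        generate(spec_dmr(10, 1.0, 0.0, remove_singletons=True), 0)


def test_dmr_singleton_removal_yields_no_isolates():
    g = generate(spec_dmr(200, 0.5, 0.1, remove_singletons=True), 3)
    assert g.number_of_nodes() == 200
    assert all(g.degree(v) > 0 for v in g)


# ---------------------------------------------------------------------------
# triangle closure


def test_triangle_closure_probability_rule():
    assert triangle_closure_probability(0, 0.3, 0.1, 0.05) == pytest.approx(0.3)
    assert triangle_closure_probability(1, 0.3, 0.1, 0.05) == pytest.approx(0.4)
    assert triangle_closure_probability(3, 0.9, 0.2, 0.1) == 1.0
    with pytest.raises(ValueError):
        triangle_closure_probability(-1, 0.3, 0.1, 0.05)


def test_triangle_closure_exact_counts(rng):
    a = generate_adjacency(spec_tc(100, 2000), rng)
    assert a.shape == (100, 100)
    assert a.sum() / 2 == 2000
    assert not a.diagonal().any()
    g0 = generate(spec_tc(7, 0), 0)
    assert g0.number_of_nodes() == 7 and g0.number_of_edges() == 0


def test_triangle_closure_validation():
    with pytest.raises(ValueError, match="m must"):
        spec_tc(4, 7)
    with pytest.raises(RuntimeError, match="rejected"):
        generate(spec_tc(30, 20, p0=0.0, p1=0.0, p_delta=0.0), 0)


# ---------------------------------------------------------------------------
# cross-family contracts


ALL_SPECS = [
    spec_er(60, 0.1),
    spec_dmc(60, 0.2, 0.1),
    spec_dmr(60, 0.2, 0.1),
    spec_dmr(60, 0.2, 0.1, remove_singletons=True),
    spec_tc(60, 150),
    ModelSpec("dmr", n=80, seed=SeedSpec("two_clique_composite"),
              params={"q_del": 0.3, "q_new": 0.1}),
    ModelSpec("er_growth", n=60, seed=SeedSpec("inverse_geometric", n0=40, d=2, R=1.5),
              params={"p": 0.05}),
]


@pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: f"{s.family}-{s.seed.kind if s.seed else 'none'}")
def test_generators_simple_graph_exact_node_count(spec):
    a = generate_adjacency(spec, 42)
    assert a.shape == (spec.n, spec.n)
    assert np.array_equal(a, a.T)
    assert not a.diagonal().any()


@pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: f"{s.family}-{s.seed.kind if s.seed else 'none'}")
def test_generators_bit_reproducible(spec):
    a1 = generate_adjacency(spec, 99)
    a2 = generate_adjacency(spec, 99)
    assert np.array_equal(a1, a2)


def test_model_spec_roundtrip_and_validation():
    spec = ModelSpec(
        "dmr",
        n=500,
        seed=SeedSpec("inverse_geometric", n0=40, d=2, R=1.5),
        params={"q_del": 0.3, "q_new": 1.0},
        remove_singletons=True,
    )
    assert ModelSpec.from_dict(spec.to_dict()) == spec
    with pytest.raises(ValueError, match="unknown family"):
        ModelSpec("barabasi", n=10, seed=SeedSpec("complete", k=2), params={})
    with pytest.raises(ValueError, match="requires parameters"):
        ModelSpec("dmc", n=10, seed=SeedSpec("complete", k=2), params={"q_mod": 0.1})
    with pytest.raises(ValueError, match="outside"):
        spec_er(50, 1.5)
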