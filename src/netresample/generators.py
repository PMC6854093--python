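"""Mechanistic network simulators and seed-network constructors.

Four generative families are implemented, all growing a simple undirected
graph to a requested node count ``n``:

``er_growth``
    Erdos-Renyi growth: starting from a seed graph, each new node links to
    every existing node independently with probability ``p``.  With a
    single-node seed this is exactly the G(n, p) model.

``dmc``
    Duplication-mutation-complementation.  Each step duplicates a uniformly
    chosen node's neighbourhood; for each neighbour, one of the two
    parallel-role edges (original-neighbour or copy-neighbour, chosen
    uniformly) is removed with probability ``q_mod``; finally the original
    and the copy are linked with probability ``q_con``.

``dmr``
    Duplication with random mutation.  Each copied edge is deleted
    independently with probability ``q_del``; then every node present at the
    start of the step receives an edge to the new node independently with
    probability ``q_new / n(t)`` (``n(t)`` the node count at step start), so
    each step adds ``q_new`` random edges in expectation.  With
    ``remove_singletons`` a new node that ends the step with degree zero is
    discarded and the step does not count, mirroring fitted models in the
    protein-interaction literature.

``triangle_closure``
    A G(n, m) variant: edges are proposed between uniformly chosen
    non-adjacent pairs and accepted with a probability that starts at ``p0``,
    rises by ``p1`` if the edge would close at least one triangle and by
    ``p_delta`` for every additional triangle closed, until ``m`` edges
    exist.  With ``p1 = p_delta = 0`` the accepted graph is exactly uniform
    G(n, m).

All generators are deterministic given a :class:`numpy.random.Generator`
(or integer seed) and return graphs with integer node labels ``0..n-1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .graph import graph_from_adjacency

__all__ = [
    "SeedSpec",
    "ModelSpec",
    "seed_complete",
    "seed_two_clique_composite",
    "seed_inverse_geometric",
    "build_seed",
    "triangle_closure_probability",
    "generate",
    "generate_adjacency",
    "generate_er_growth",
    "generate_dmc",
    "generate_dmr",
    "generate_triangle_closure",
]

FAMILIES = ("er_growth", "dmc", "dmr", "triangle_closure")

_REQUIRED_PARAMS = {
    "er_growth": ("p",),
    "dmc": ("q_mod", "q_con"),
    "dmr": ("q_del", "q_new"),
    "triangle_closure": ("p0", "p1", "p_delta"),
}

#: steps attempted per requested node before a DMR run is declared stuck
DMR_ATTEMPT_FACTOR = 100
#: probability rejections tolerated per requested edge in triangle closure
TRIANGLE_CLOSURE_ATTEMPT_FACTOR = 1000


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# seed networks


@dataclass(frozen=True)
class SeedSpec:
    """Specification of the seed network a mechanistic model grows from.

    ``kind`` is one of ``complete`` (K_k), ``two_clique_composite`` (the
    50-node seed built from highly connected 7- and 10-cliques plus 33
    pendant nodes), ``inverse_geometric`` (n0 standard-normal points in
    R^d, edge when the pairwise distance exceeds R) or ``explicit`` (a
    user-supplied graph, by object or edge-list path).
    """

    kind: str
    k: int | None = None
    n0: int | None = None
    d: int | None = None
    R: float | None = None
    graph: nx.Graph | None = None
    path: str | None = None
    connect_within: bool = False

    def __post_init__(self) -> None:
        if self.kind == "complete":
            if self.k is None or self.k < 1:
                raise ValueError("complete seed requires k >= 1")
        elif self.kind == "two_clique_composite":
            pass
        elif self.kind == "inverse_geometric":
            if self.n0 is None or self.n0 < 1:
                raise ValueError("inverse_geometric seed requires n0 >= 1")
            if self.d is None or self.d < 1:
                raise ValueError("inverse_geometric seed requires d >= 1")
            if self.R is None or self.R < 0:
                raise ValueError("inverse_geometric seed requires R >= 0")
        elif self.kind == "explicit":
            if self.graph is None and self.path is None:
                raise ValueError("explicit seed requires a graph or a path")
        else:
            raise ValueError(f"unknown seed kind {self.kind!r}")

    @property
    def size(self) -> int:
        """Node count of the seed (fixed for every kind)."""
        if self.kind == "complete":
            return int(self.k)  # type: ignore[arg-type]
        if self.kind == "two_clique_composite":
            return 50
        if self.kind == "inverse_geometric":
            return int(self.n0)  # type: ignore[arg-type]
        return self._explicit_graph().number_of_nodes()

    def _explicit_graph(self) -> nx.Graph:
        if self.graph is not None:
            return self.graph
        from .io import read_edge_list

        g = read_edge_list(self.path)  # type: ignore[arg-type]
        object.__setattr__(self, "graph", g)
        return g

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"kind": self.kind}
        if self.kind == "complete":
            d["k"] = self.k
        elif self.kind == "inverse_geometric":
            d.update(n0=self.n0, d=self.d, R=self.R)
            if self.connect_within:
                d["connect_within"] = True
        elif self.kind == "explicit":
            d["path"] = self.path
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SeedSpec":
        return cls(**dict(d))


def seed_complete(k: int) -> nx.Graph:
    """Complete graph K_k."""
    if k < 1:
        raise ValueError("complete seed requires k >= 1")
    return nx.complete_graph(k)


def _seed_complete_adj(k: int) -> np.ndarray:
    a = np.ones((k, k), dtype=bool)
    np.fill_diagonal(a, False)
    return a


def _seed_two_clique_adj(rng: np.random.Generator) -> np.ndarray:
    # K7 on 0..6, K10 on 7..16, 70 cross-clique Bernoulli(0.67) edges,
    # then 33 pendant nodes each attached to one uniformly chosen clique node
    a = np.zeros((50, 50), dtype=bool)
    a[:7, :7] = _seed_complete_adj(7)
    a[7:17, 7:17] = _seed_complete_adj(10)
    cross = rng.random((7, 10)) < 0.67
    a[:7, 7:17] = cross
    a[7:17, :7] = cross.T
    anchors = rng.integers(0, 17, size=33)
    for leaf, anchor in enumerate(anchors, start=17):
        a[leaf, anchor] = a[anchor, leaf] = True
    return a


def seed_two_clique_composite(rng: np.random.Generator | int | None = None) -> nx.Graph:
    """50-node seed: highly connected 7- and 10-cliques plus 33 pendant nodes."""
    return graph_from_adjacency(_seed_two_clique_adj(_as_rng(rng)))


def _seed_inverse_geometric_adj(
    n0: int, d: int, R: float, rng: np.random.Generator, connect_within: bool
) -> np.ndarray:
    coords = rng.standard_normal((n0, d))
    if n0 == 1:
        return np.zeros((1, 1), dtype=bool)
    dist = squareform(pdist(coords))
    a = (dist < R) if connect_within else (dist > R)
    np.fill_diagonal(a, False)
    return a


def seed_inverse_geometric(
    n0: int,
    d: int,
    R: float,
    rng: np.random.Generator | int | None = None,
    *,
    connect_within: bool = False,
) -> nx.Graph:
    """Inverse geometric seed: i.i.d. N(0, I_d) coordinates, edge iff distance > R.

    The "greater than" rule inverts the usual geometric-graph convention but
    is implemented as stated by its source; pass ``connect_within=True`` for
    the conventional distance < R rule.
    """
    if n0 < 1:
        raise ValueError("inverse_geometric seed requires n0 >= 1")
    return graph_from_adjacency(
        _seed_inverse_geometric_adj(n0, d, R, _as_rng(rng), connect_within)
    )


def _seed_adjacency(seed: SeedSpec, rng: np.random.Generator) -> np.ndarray:
    if seed.kind == "complete":
        return _seed_complete_adj(int(seed.k))  # type: ignore[arg-type]
    if seed.kind == "two_clique_composite":
        return _seed_two_clique_adj(rng)
    if seed.kind == "inverse_geometric":
        return _seed_inverse_geometric_adj(
            int(seed.n0), int(seed.d), float(seed.R), rng, seed.connect_within  # type: ignore[arg-type]
        )
    g = seed._explicit_graph()
    return nx.to_numpy_array(g, dtype=float) > 0


def build_seed(seed: SeedSpec, rng: np.random.Generator | int | None = None) -> nx.Graph:
    """Materialise a seed network from its specification."""
    return graph_from_adjacency(_seed_adjacency(seed, _as_rng(rng)))


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ModelSpec:
    """A candidate generative model: family, parameters, seed and target size."""

    family: str
    n: int
    seed: SeedSpec | None = None
    m: int | None = None
    params: Mapping[str, float] = field(default_factory=dict)
    remove_singletons: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        missing = [p for p in _REQUIRED_PARAMS[self.family] if p not in self.params]
        if missing:
            raise ValueError(f"{self.family} requires parameters {missing}")
        for key, val in self.params.items():
            if key in ("p_delta", "q_new"):
                # p_delta is an increment; q_new an expected number of random
                # edges per step (the per-node probability is q_new / n(t))
                if val < 0:
                    raise ValueError(f"{key} must be >= 0")
            elif not 0.0 <= float(val) <= 1.0:
                raise ValueError(f"parameter {key}={val} outside [0, 1]")
        if self.family == "triangle_closure":
            if self.n < 2:
                raise ValueError("triangle_closure requires n >= 2")
            if self.m is None:
                raise ValueError("triangle_closure requires a target edge count m")
            if self.m < 0 or self.m > self.n * (self.n - 1) // 2:
                raise ValueError("m must satisfy 0 <= m <= n(n-1)/2")
        else:
            if self.seed is None:
                raise ValueError(f"{self.family} requires a seed network spec")
            if self.n < self.seed.size:
                raise ValueError(
                    f"target n={self.n} smaller than seed size {self.seed.size}"
                )

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "family": self.family,
            "n": self.n,
            "params": dict(self.params),
        }
        if self.m is not None:
            d["m"] = self.m
        if self.seed is not None:
            d["seed"] = self.seed.to_dict()
        if self.remove_singletons:
            d["remove_singletons"] = True
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelSpec":
        d = dict(d)
        seed = d.pop("seed", None)
        if seed is not None:
            seed = SeedSpec.from_dict(seed)
        return cls(
            family=d.pop("family"),
            n=int(d.pop("n")),
            seed=seed,
            m=(int(d["m"]) if d.get("m") is not None else None) if "m" in d else None,
            params={k: float(v) for k, v in dict(d.pop("params", {})).items()},
            remove_singletons=bool(d.pop("remove_singletons", False)),
        )


# ---------------------------------------------------------------------------
# growth mechanisms (adjacency-matrix implementations)


def _grow_er(a0: np.ndarray, n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    k = a0.shape[0]
    a = np.zeros((n, n), dtype=bool)
    a[:k, :k] = a0
    for t in range(k, n):
        row = rng.random(t) < p
        a[t, :t] = row
        a[:t, t] = row
    return a


def _grow_dmc(
    a0: np.ndarray,
    n: int,
    q_mod: float,
    q_con: float,
    rng: np.random.Generator,
    edge_trace: list[int] | None = None,
) -> np.ndarray:
    k = a0.shape[0]
    a = np.zeros((n, n), dtype=bool)
    a[:k, :k] = a0
    m = int(np.count_nonzero(a0) // 2)
    if edge_trace is not None:
        edge_trace.append(m)
    for t in range(k, n):
        u = int(rng.integers(t))
        nb = np.flatnonzero(a[u, :t])
        a[t, nb] = True
        a[nb, t] = True
        m += nb.size
        if nb.size:
            rem = rng.random(nb.size) < q_mod
            # uniformly pick which of the two parallel-role edges goes
            hit_copy = rng.random(nb.size) < 0.5
            drop_copy = nb[rem & hit_copy]
            drop_orig = nb[rem & ~hit_copy]
            a[t, drop_copy] = False
            a[drop_copy, t] = False
            a[u, drop_orig] = False
            a[drop_orig, u] = False
            m -= drop_copy.size + drop_orig.size
        if rng.random() < q_con:
            a[t, u] = a[u, t] = True
            m += 1
        if edge_trace is not None:
            edge_trace.append(m)
    return a


def _grow_dmr(
    a0: np.ndarray,
    n: int,
    q_del: float,
    q_new: float,
    remove_singletons: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    k = a0.shape[0]
    a = np.zeros((n, n), dtype=bool)
    a[:k, :k] = a0
    cur = k
    attempts = 0
    cap = DMR_ATTEMPT_FACTOR * max(n, 1)
    while cur < n:
        attempts += 1
        if attempts > cap:
            raise RuntimeError(
                f"DMR did not reach n={n} within {cap} steps; with "
                "remove_singletons, q_del close to 1 and q_new close to 0 "
                "every new node is discarded as a singleton"
            )
        u = int(rng.integers(cur))
        nb = np.flatnonzero(a[u, :cur])
        row = np.zeros(cur, dtype=bool)
        if nb.size:
            row[nb[rng.random(nb.size) >= q_del]] = True
        # one independent q_new/n(t) trial per node present at step start;
        # a success on an already-copied pair changes nothing
        row |= rng.random(cur) < q_new / cur
        if remove_singletons and not row.any():
            continue
        a[cur, :cur] = row
        a[:cur, cur] = row
        cur += 1
    return a


def triangle_closure_probability(
    t: int, p0: float, p1: float, p_delta: float
) -> float:
    """Acceptance probability for an edge closing ``t`` triangles.

    ``p0`` if no triangle is closed, ``p0 + p1 + (t - 1) * p_delta``
    otherwise, clamped to [0, 1].
    """
    if t < 0:
        raise ValueError("triangle count must be non-negative")
    p = p0 if t == 0 else p0 + p1 + (t - 1) * p_delta
    return min(1.0, max(0.0, p))


def _grow_triangle_closure(
    n: int,
    m: int,
    p0: float,
    p1: float,
    p_delta: float,
    rng: np.random.Generator,
) -> np.ndarray:
    a = np.zeros((n, n), dtype=bool)
    edges = 0
    rejections = 0
    cap = TRIANGLE_CLOSURE_ATTEMPT_FACTOR * max(m, 1)
    batch = 256
    while edges < m:
        pi = rng.integers(0, n, size=batch)
        pj = rng.integers(0, n, size=batch)
        coins = rng.random(batch)
        for i, j, u in zip(pi.tolist(), pj.tolist(), coins.tolist()):
            if edges >= m:
                break
            if i == j or a[i, j]:
                continue
            t = int(np.count_nonzero(a[i] & a[j]))
            p = p0 if t == 0 else p0 + p1 + (t - 1) * p_delta
            if u < p:
                a[i, j] = a[j, i] = True
                edges += 1
            else:
                rejections += 1
                if rejections > cap:
                    raise RuntimeError(
                        f"triangle closure rejected {rejections} proposals "
                        f"before reaching m={m}; acceptance probabilities may "
                        "be (near) zero for this parameterisation"
                    )
    return a


# ---------------------------------------------------------------------------
# public dispatch


def generate_adjacency(
    spec: ModelSpec,
    rng: np.random.Generator | int | None = None,
    *,
    edge_trace: list[int] | None = None,
) -> np.ndarray:
    """Draw one network from ``spec`` as a boolean adjacency matrix.

    ``edge_trace`` (DMC only) receives the edge count after every growth
    step, seed included.
    """
    r = _as_rng(rng)
    p = spec.params
    if spec.family == "triangle_closure":
        return _grow_triangle_closure(
            spec.n, int(spec.m), p["p0"], p["p1"], p["p_delta"], r  # type: ignore[arg-type]
        )
    a0 = _seed_adjacency(spec.seed, r)  # type: ignore[arg-type]
    if spec.family == "er_growth":
        return _grow_er(a0, spec.n, p["p"], r)
    if spec.family == "dmc":
        return _grow_dmc(a0, spec.n, p["q_mod"], p["q_con"], r, edge_trace)
    return _grow_dmr(a0, spec.n, p["q_del"], p["q_new"], spec.remove_singletons, r)


def generate(
    spec: ModelSpec, rng: np.random.Generator | int | None = None
) -> nx.Graph:
    """Draw one network from ``spec`` as a networkx graph on nodes ``0..n-1``."""
    return graph_from_adjacency(generate_adjacency(spec, rng))


def generate_er_growth(spec: ModelSpec, rng=None) -> nx.Graph:
    if spec.family != "er_growth":
        raise ValueError("spec.family must be 'er_growth'")
    return generate(spec, rng)


def generate_dmc(spec: ModelSpec, rng=None, *, edge_trace: list[int] | None = None) -> nx.Graph:
    if spec.family != "dmc":
        raise ValueError("spec.family must be 'dmc'")
    return graph_from_adjacency(generate_adjacency(spec, rng, edge_trace=edge_trace))


def generate_dmr(spec: ModelSpec, rng=None) -> nx.Graph:
    if spec.family != "dmr":
        raise ValueError("spec.family must be 'dmr'")
    return generate(spec, rng)


def generate_triangle_closure(spec: ModelSpec, rng=None) -> nx.Graph:
    if spec.family != "triangle_closure":
        raise ValueError("spec.family must be 'triangle_closure'")
    return generate(spec, rng)
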