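"""Undirected-graph statistics used as resampling features.

Graphs are plain :class:`networkx.Graph` objects with opaque node labels;
every public statistic also accepts a dense adjacency matrix, which is the
fast path the resampling machinery uses internally (subsampling a graph
thousands of times is much cheaper on a numpy array than on a networkx
view).

Statistics are addressed through a string registry so that the subsampling
pipeline, the CLI and the reports all agree on names.  The built-in
identifiers are ``avg_clustering``, ``triangles``, ``assortativity`` and
``deg_q25`` / ``deg_q50`` / ``deg_q75``; users may register their own with
:func:`register_statistic`.

A statistic may be undefined on a degenerate input (degree assortativity on
a regular graph has zero variance in the endpoint degrees); such values are
returned as ``nan`` rather than silently coerced to a number, and the
resampling layer drops and counts the affected rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "StatVector",
    "Statistic",
    "average_local_clustering",
    "triangle_count",
    "degree_assortativity",
    "degree_quantiles",
    "largest_connected_component",
    "compute_stat_vector",
    "stat_row_from_adjacency",
    "register_statistic",
    "registered_statistics",
    "to_adjacency",
    "graph_from_adjacency",
    "DEFAULT_GOF_STATS",
    "SELECTION_STATS",
]

#: statistics the goodness-of-fit workflow compares by default
DEFAULT_GOF_STATS = ("avg_clustering", "triangles", "assortativity")
#: predictor set used for model selection: local clustering, triangle count
#: and the three quartiles of the degree distribution
SELECTION_STATS = ("avg_clustering", "triangles", "deg_q25", "deg_q50", "deg_q75")


def to_adjacency(g: nx.Graph | np.ndarray) -> np.ndarray:
    """Return a dense float adjacency matrix for ``g`` (symmetric, zero diagonal)."""
    if isinstance(g, np.ndarray):
        return np.asarray(g, dtype=float)
    return nx.to_numpy_array(g, dtype=float)


def graph_from_adjacency(a: np.ndarray) -> nx.Graph:
    """Build a simple graph on nodes ``0..n-1`` from a (boolean or weighted) adjacency."""
    a = np.asarray(a)
    g = nx.Graph()
    g.add_nodes_from(range(a.shape[0]))
    ii, jj = np.nonzero(np.triu(a, 1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return g


def _require_nonempty(a: np.ndarray) -> None:
    if a.shape[0] == 0:
        raise ValueError("no nodes")


def _triangles_per_node(a: np.ndarray) -> np.ndarray:
    # (A @ A * A).sum(1) counts, for each node i, ordered pairs of adjacent
    # neighbours; halving gives triangles through i.
    return (a @ a * a).sum(axis=1) / 2.0


def average_local_clustering(g: nx.Graph | np.ndarray) -> float:
    """Mean over nodes of (edges among neighbours) / C(deg, 2).

    Nodes with degree < 2 have no neighbour pair and contribute 0, so a star
    has average local clustering 0 and any complete graph on >= 3 nodes has 1.
    """
    a = to_adjacency(g)
    _require_nonempty(a)
    deg = a.sum(axis=1)
    tri = _triangles_per_node(a)
    coef = np.zeros_like(deg)
    mask = deg >= 2
    coef[mask] = tri[mask] / (deg[mask] * (deg[mask] - 1) / 2.0)
    return float(coef.mean())


def triangle_count(g: nx.Graph | np.ndarray) -> int:
    """Number of unordered node triples with all three edges present."""
    a = to_adjacency(g)
    if a.shape[0] == 0:
        return 0
    return int(round(_triangles_per_node(a).sum() / 3.0))


def degree_assortativity(g: nx.Graph | np.ndarray) -> float:
    """Pearson correlation of endpoint degrees over edges.

    Each edge contributes both orientations, so the correlation is computed
    on the symmetric multiset of ordered endpoint-degree pairs.  Returns
    ``nan`` when the endpoint degrees have zero variance (e.g. any regular
    graph), which callers must treat as *undefined*, not as zero.
    """
    a = to_adjacency(g)
    _require_nonempty(a)
    deg = a.sum(axis=1)
    ii, jj = np.nonzero(np.triu(a, 1))
    if ii.size == 0:
        raise ValueError("degree assortativity requires at least one edge")
    x = np.concatenate([deg[ii], deg[jj]])
    y = np.concatenate([deg[jj], deg[ii]])
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0.0:
        return float("nan")
    return float((xc * yc).sum() / denom)


def degree_quantiles(
    g: nx.Graph | np.ndarray, probs: Sequence[float]
) -> np.ndarray:
    """Empirical quantiles of the degree sequence at ``probs``.

    Uses numpy's linear-interpolation convention on the sorted degrees; the
    convention is fixed so that training and test features of the model
    selector are computed identically.
    """
    a = to_adjacency(g)
    _require_nonempty(a)
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        return np.empty(0)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("quantile probabilities must lie in [0, 1]")
    return np.quantile(a.sum(axis=1), probs, method="linear")


def largest_connected_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest component by node count.

    Ties are broken in favour of the component containing the
    lexicographically smallest node label (labels compared as strings), so
    the result is deterministic.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("no nodes")
    comps = list(nx.connected_components(g))
    best = max(len(c) for c in comps)
    winners = [c for c in comps if len(c) == best]
    chosen = min(winners, key=lambda c: min(str(v) for v in c))
    return g.subgraph(chosen).copy()


# ---------------------------------------------------------------------------
# statistic registry


@dataclass(frozen=True)
class Statistic:
    """A named scalar graph statistic.

    ``from_graph`` computes the value from a networkx graph; the optional
    ``from_adjacency`` fast path computes it from a dense adjacency matrix
    and is what the resampling loops call.
    """

    name: str
    from_graph: Callable[[nx.Graph], float]
    from_adjacency: Callable[[np.ndarray], float] | None = None

    def __call__(self, g: nx.Graph | np.ndarray) -> float:
        if isinstance(g, np.ndarray):
            if self.from_adjacency is not None:
                return float(self.from_adjacency(g))
            return float(self.from_graph(graph_from_adjacency(g)))
        return float(self.from_graph(g))


def _assortativity_or_nan(a: np.ndarray) -> float:
    # subsamples may have no edges at all; treat that as undefined, like
    # the zero-variance case, so the row is dropped rather than erroring
    if np.count_nonzero(np.triu(a, 1)) == 0:
        return float("nan")
    return degree_assortativity(a)


def _quantile_stat(p: float) -> Callable[[np.ndarray], float]:
    def f(a: np.ndarray) -> float:
        return float(degree_quantiles(a, (p,))[0])

    return f


_REGISTRY: dict[str, Statistic] = {}


def register_statistic(
    name: str,
    from_graph: Callable[[nx.Graph], float],
    from_adjacency: Callable[[np.ndarray], float] | None = None,
    *,
    overwrite: bool = False,
) -> Statistic:
    """Add a user statistic to the registry under ``name``."""
    if name in _REGISTRY and not overwrite:
        raise ValueError(f"statistic {name!r} already registered")
    stat = Statistic(name, from_graph, from_adjacency)
    _REGISTRY[name] = stat
    return stat


def unregister_statistic(name: str) -> None:
    _REGISTRY.pop(name, None)


def registered_statistics() -> tuple[str, ...]:
    return tuple(_REGISTRY)


def get_statistic(name: str) -> Statistic:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown statistic {name!r}; registered: {', '.join(sorted(_REGISTRY))}"
        ) from None


for _name, _fg, _fa in [
    ("avg_clustering", average_local_clustering, average_local_clustering),
    ("triangles", triangle_count, triangle_count),
    ("assortativity", lambda g: _assortativity_or_nan(to_adjacency(g)), _assortativity_or_nan),
    ("deg_q25", lambda g: float(degree_quantiles(g, (0.25,))[0]), _quantile_stat(0.25)),
    ("deg_q50", lambda g: float(degree_quantiles(g, (0.50,))[0]), _quantile_stat(0.50)),
    ("deg_q75", lambda g: float(degree_quantiles(g, (0.75,))[0]), _quantile_stat(0.75)),
]:
    _REGISTRY[_name] = Statistic(_name, _fg, _fa)


@dataclass(frozen=True)
class StatVector:
    """An ordered vector of named statistic values for one graph."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.names) != len(set(self.names)):
            raise ValueError("statistic names must be unique")
        if len(self.names) != self.values.shape[0]:
            raise ValueError("names and values must have equal length")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def compute_stat_vector(
    g: nx.Graph | np.ndarray, stats: Iterable[str]
) -> StatVector:
    """Evaluate the registered statistics ``stats`` on ``g``, in order."""
    names = tuple(stats)
    funcs = [get_statistic(n) for n in names]
    return StatVector(names, np.array([f(g) for f in funcs]))


def stat_row_from_adjacency(a: np.ndarray, stats: Sequence[str]) -> np.ndarray:
    """Fast path: evaluate ``stats`` on a dense adjacency matrix."""
    a = np.asarray(a, dtype=float)
    return np.array([get_statistic(n)(a) for n in stats])
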