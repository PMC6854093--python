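"""Node-wise subsampling and the three resampling distributions.

A subsample is a uniform without-replacement draw of ``max(1,
floor(fraction * n))`` nodes together with its induced subgraph.  Three
resampling distributions of graph statistics are built from subsamples:

* ``F_o`` (*observed*): many subsamples of the single observed network;
* ``F_c`` (*model_independent*): one subsample from each of many
  independent draws from a candidate model;
* ``F_1`` (*model_single_draw*): many subsamples of one single model draw.

The observed network and the model draws are always subsampled at the same
fraction so both sides carry the same amount of missingness and their
distributions are comparable.

Randomness is organised as one :class:`numpy.random.SeedSequence` substream
per row, derived from ``(scheme.seed, row index)``, so the rows are
independent, the matrices are bit-reproducible, and row evaluation could be
parallelised without changing results.

Rows in which some statistic is undefined (``nan`` -- e.g. degree
assortativity on a regular induced subgraph) are dropped and counted in
``n_dropped`` rather than imputed, which would distort the distribution.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .generators import ModelSpec, generate_adjacency
from .graph import stat_row_from_adjacency, to_adjacency

__all__ = [
    "SubsampleScheme",
    "ResamplingDistribution",
    "node_subsample",
    "subsample_size",
    "build_observed_distribution",
    "build_model_distribution",
    "fraction_diagnostic",
]

logger = logging.getLogger(__name__)

PROVENANCES = ("observed", "model_independent", "model_single_draw")


@dataclass(frozen=True)
class SubsampleScheme:
    """Subsampling design: node fraction, replicate counts and RNG seed.

    ``b_obs`` subsamples are taken from an observed network; ``b_model``
    controls the model side (number of independent draws, or of subsamples
    of the single draw).  The default fraction of 0.3 follows the guidance
    to keep the subsampled portion low while retaining model features; the
    scaled Table 1 replication overrides it to 0.8.
    """

    fraction: float = 0.3
    b_obs: int = 100
    b_model: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must lie in (0, 1]")
        if self.b_obs < 1 or self.b_model < 1:
            raise ValueError("replicate counts must be >= 1")

    def with_seed(self, seed: int | None) -> "SubsampleScheme":
        return replace(self, seed=seed)


def subsample_size(n: int, fraction: float) -> int:
    """Nodes per subsample: ``max(1, floor(fraction * n))``."""
    return max(1, math.floor(fraction * n))


def node_subsample(
    g: nx.Graph, fraction: float, rng: np.random.Generator | int | None = None
) -> nx.Graph:
    """Induced subgraph on a uniform without-replacement node sample."""
    if g.number_of_nodes() == 0:
        raise ValueError("cannot subsample an empty graph")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    nodes = list(g.nodes)
    size = subsample_size(len(nodes), fraction)
    picked = rng.choice(len(nodes), size=size, replace=False)
    return g.subgraph([nodes[i] for i in picked]).copy()


@dataclass
class ResamplingDistribution:
    """A B x |S| matrix of statistic values over subsamples.

    ``values[b, s]`` is statistic ``stat_names[s]`` on subsample ``b``;
    ``provenance`` records which of F_o / F_c / F_1 this is.
    """

    values: np.ndarray
    stat_names: tuple[str, ...]
    provenance: str
    scheme: SubsampleScheme
    source: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(
            -1, len(self.stat_names)
        )
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.stat_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.stat_names))

    def summary(self, probs: Sequence[float] = (0.025, 0.25, 0.5, 0.75, 0.975)) -> pd.DataFrame:
        """Location/spread quantiles of every statistic column."""
        if self.n_rows == 0:
            return pd.DataFrame(index=list(probs), columns=list(self.stat_names), dtype=float)
        q = np.quantile(self.values, probs, axis=0)
        return pd.DataFrame(q, index=list(probs), columns=list(self.stat_names))

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix as TSV with a provenance comment block."""
        sc = self.scheme
        header = [
            f"# provenance: {self.provenance}",
            f"# scheme: fraction={sc.fraction} b_obs={sc.b_obs} "
            f"b_model={sc.b_model} seed={sc.seed}",
            f"# source: {self.source}",
            f"# dropped: {self.n_dropped}",
        ]
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            fh.write("\t".join(self.stat_names) + "\n")
            for row in self.values:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResamplingDistribution":
        meta: dict[str, str] = {}
        rows: list[list[float]] = []
        names: tuple[str, ...] | None = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line[1:].partition(":")
                    meta[key.strip()] = val.strip()
                elif names is None:
                    names = tuple(line.split("\t"))
                else:
                    rows.append([float(v) for v in line.split("\t")])
        if names is None:
            raise ValueError(f"no header line in {path}")
        sc_fields = dict(
            item.split("=", 1) for item in meta.get("scheme", "").split() if "=" in item
        )
        seed = sc_fields.get("seed", "None")
        scheme = SubsampleScheme(
            fraction=float(sc_fields.get("fraction", 0.3)),
            b_obs=int(sc_fields.get("b_obs", 100)),
            b_model=int(sc_fields.get("b_model", 100)),
            seed=None if seed == "None" else int(seed),
        )
        return cls(
            values=np.array(rows, dtype=float).reshape(-1, len(names)),
            stat_names=names,
            provenance=meta.get("provenance", "observed"),
            scheme=scheme,
            source=meta.get("source", ""),
            n_dropped=int(meta.get("dropped", 0)),
        )


def _row_streams(seed: int | None, count: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(count)
    return [np.random.default_rng(c) for c in children]


def _collect_rows(row_iter: Iterable[np.ndarray], what: str) -> tuple[np.ndarray, int]:
    kept: list[np.ndarray] = []
    dropped = 0
    for row in row_iter:
        if np.all(np.isfinite(row)):
            kept.append(row)
        else:
            dropped += 1
    if dropped:
        logger.info("%s: dropped %d subsample(s) with undefined statistics", what, dropped)
    values = np.array(kept, dtype=float)
    return values, dropped


def build_observed_distribution(
    g: nx.Graph | np.ndarray,
    stats: Sequence[str],
    scheme: SubsampleScheme,
    *,
    source: str = "observed network",
) -> ResamplingDistribution:
    """``F_o``: statistics of ``scheme.b_obs`` subsamples of one network."""
    a = to_adjacency(g)
    n = a.shape[0]
    if n == 0:
        raise ValueError("cannot subsample an empty graph")
    names = tuple(stats)
    size = subsample_size(n, scheme.fraction)

    def rows():
        for rng in _row_streams(scheme.seed, scheme.b_obs):
            # sorted: the node set is what matters, and a fixed order keeps
            # float summation identical across draws of the same set
            idx = np.sort(rng.choice(n, size=size, replace=False))
            yield stat_row_from_adjacency(a[np.ix_(idx, idx)], names)

    values, dropped = _collect_rows(rows(), source)
    return ResamplingDistribution(values, names, "observed", scheme, source, dropped)


def build_model_distribution(
    spec: ModelSpec,
    stats: Sequence[str],
    scheme: SubsampleScheme,
    mode: str = "independent",
) -> ResamplingDistribution:
    """``F_c`` (``mode='independent'``) or ``F_1`` (``mode='single_draw'``).

    Independent mode draws ``scheme.b_model`` networks and takes exactly one
    subsample from each; single-draw mode draws one network and takes
    ``scheme.b_model`` subsamples of it.  Both subsample at
    ``scheme.fraction`` of the model's ``n`` nodes.
    """
    if mode not in ("independent", "single_draw"):
        raise ValueError("mode must be 'independent' or 'single_draw'")
    names = tuple(stats)
    size = subsample_size(spec.n, scheme.fraction)

    if mode == "independent":
        def rows():
            for b, rng in enumerate(_row_streams(scheme.seed, scheme.b_model)):
                try:
                    a = generate_adjacency(spec, rng).astype(float)
                except Exception as exc:
                    raise RuntimeError(f"model draw {b} failed: {exc}") from exc
                idx = np.sort(rng.choice(spec.n, size=size, replace=False))
                yield stat_row_from_adjacency(a[np.ix_(idx, idx)], names)

        provenance = "model_independent"
    else:
        streams = _row_streams(scheme.seed, scheme.b_model + 1)
        a_single = generate_adjacency(spec, streams[0]).astype(float)

        def rows():
            for rng in streams[1:]:
                idx = np.sort(rng.choice(spec.n, size=size, replace=False))
                yield stat_row_from_adjacency(a_single[np.ix_(idx, idx)], names)

        provenance = "model_single_draw"

    source = f"{spec.family}(n={spec.n})"
    values, dropped = _collect_rows(rows(), f"{provenance} {source}")
    return ResamplingDistribution(values, names, provenance, scheme, source, dropped)


def fraction_diagnostic(
    spec: ModelSpec,
    stats: Sequence[str],
    fractions: Sequence[float],
    scheme: SubsampleScheme,
    replicates: int = 3,
) -> pd.DataFrame:
    """Mean KS distance between F_1 and F_c as a function of the fraction.

    For each fraction, ``replicates`` independent (F_1, F_c) pairs are built
    and the per-statistic KS statistic is averaged.  Small values mean
    subsamples of a single model draw already behave like subsamples of
    independent draws, i.e. the fraction retains model features without
    over-committing to one realisation; the table is used to pick a working
    fraction.
    """
    from .distances import ks_statistic

    fractions = list(fractions)
    if any(not 0.0 < f < 1.0 for f in fractions):
        raise ValueError("diagnostic fractions must lie in (0, 1)")
    if scheme.b_model < 30:
        warnings.warn(
            "fraction_diagnostic with b_model < 30 gives very noisy KS values",
            stacklevel=2,
        )
    names = tuple(stats)
    base = np.random.SeedSequence(scheme.seed)
    out = np.zeros((len(fractions), len(names)))
    for i, frac in enumerate(fractions):
        acc = np.zeros(len(names))
        used = 0
        for rep_seed in base.spawn(replicates):
            s1, s2 = rep_seed.spawn(2)
            sc = replace(scheme, fraction=frac)
            f1 = build_model_distribution(
                spec, names, sc.with_seed(int(s1.generate_state(1)[0])), "single_draw"
            )
            fc = build_model_distribution(
                spec, names, sc.with_seed(int(s2.generate_state(1)[0])), "independent"
            )
            if f1.n_rows == 0 or fc.n_rows == 0:
                continue
            acc += [
                ks_statistic(f1.column(nm), fc.column(nm)) for nm in names
            ]
            used += 1
        out[i] = acc / max(used, 1)
    return pd.DataFrame(out, index=pd.Index(fractions, name="fraction"), columns=list(names))
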