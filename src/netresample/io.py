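"""Edge-list I/O and model-spec configuration files.

The edge-list dialect is plain text: one edge per line as two
whitespace-separated node labels, ``#`` comment lines, and an optional
``%ISOLATED`` section listing degree-0 nodes one per line (a bare edge list
cannot represent them, and DMR with singleton retention produces them).
Node labels are read as opaque strings and never silently reindexed;
writing uses ``str(label)`` with lexicographically sorted endpoints and
lines, so ``read(write(g))`` reproduces ``g`` up to string labels.

Model specifications are YAML mappings mirroring
:meth:`~netresample.generators.ModelSpec.to_dict`::

    family: dmr
    n: 5000
    params: {q_del: 0.365, q_new: 0.12}
    remove_singletons: true
    seed: {kind: two_clique_composite}
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any

import networkx as nx
import yaml

from .generators import ModelSpec

__all__ = ["read_edge_list", "write_edge_list", "load_model_spec", "dump_model_spec"]

logger = logging.getLogger(__name__)

ISOLATED_MARKER = "%ISOLATED"


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a simple undirected graph; labels stay strings.

    Self-loops and duplicate edges are dropped with a logged count; a
    malformed (single-token) line raises with its line number.
    """
    g = nx.Graph()
    loops = 0
    dupes = 0
    in_isolated = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == ISOLATED_MARKER:
                in_isolated = True
                continue
            parts = line.split()
            if in_isolated:
                if len(parts) != 1:
                    raise ValueError(
                        f"{path}:{lineno}: expected one node label per line "
                        f"in the {ISOLATED_MARKER} section, got {len(parts)}"
                    )
                g.add_node(parts[0])
                continue
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two node labels, got {line!r}"
                )
            u, v = parts[0], parts[1]
            if u == v:
                loops += 1
                continue
            if g.has_edge(u, v):
                dupes += 1
                continue
            g.add_edge(u, v)
    if loops:
        logger.info("%s: dropped %d self-loop(s)", path, loops)
    if dupes:
        logger.info("%s: dropped %d duplicate edge(s)", path, dupes)
    return g


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    """Write one edge per line (sorted), isolated nodes in a sidecar section."""
    lines = sorted(
        "\t".join(sorted((str(u), str(v)))) for u, v in g.edges
    )
    isolated = sorted(str(v) for v in g.nodes if g.degree(v) == 0)
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
        if isolated:
            fh.write(ISOLATED_MARKER + "\n")
            for v in isolated:
                fh.write(v + "\n")


def load_model_spec(path: str | Path) -> ModelSpec:
    """Read a :class:`ModelSpec` from a YAML mapping file."""
    with open(path) as fh:
        data: Any = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping describing a model spec")
    return ModelSpec.from_dict(data)


def dump_model_spec(spec: ModelSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=True)
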