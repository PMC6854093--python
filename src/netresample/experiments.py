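"""Reproduction harnesses for the two simulation studies.

*Selection study*: two triangle-closure models sharing ``p0 = 0.3`` and
``p1 = 0.1`` but differing in ``p_delta`` (model 1 has 0, model 2 varies
over 0.05/0.03/0.01/0.005) are pitted against each other on 100-node
networks with 100/500/1000/2000 edges.  A classifier is trained on one
80-node subsample from each of many draws per model, then every test
network is classified through 100 of its own subsamples with plurality
vote; each grid cell reports the proportion of test networks classified
correctly, plus per-network confidence in the correct model.

*Stability study*: replicate networks are grown from complete-graph seeds
of several sizes, and the replicate-to-replicate variability of the degree
distribution is summarised as the mean pairwise total-variation distance
between the replicates' empirical degree distributions (a scalar proxy for
the visual band-width assessment; duplication-divergence models destabilise
sharply as the seed shrinks, ER growth does not).

Both harnesses take a ``scale`` factor so the full-size studies (10000
training draws and 1000 test networks per model; 50 replicates over five
network sizes and six seeds) can be run at desk scale; the default scale of
0.1 gives 1000 training draws and 100 test networks per model per cell.
Scaling changes Monte-Carlo error only, not the quantities being estimated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .generators import ModelSpec, SeedSpec, generate_adjacency
from .graph import SELECTION_STATS, stat_row_from_adjacency
from .procedures import build_learner, tally_assignments
from .resampling import SubsampleScheme, build_model_distribution, subsample_size

__all__ = [
    "SelectionStudyConfig",
    "StabilityStudyConfig",
    "CellResult",
    "run_selection_cell",
    "run_selection_study",
    "run_stability_study",
    "replicate_degree_sequences",
    "mean_pairwise_tv",
    "total_variation",
    "plot_confidence_histograms",
]


@dataclass(frozen=True)
class SelectionStudyConfig:
    """Grid and sizes for the triangle-closure model-selection study."""

    p_deltas: tuple[float, ...] = (0.05, 0.03, 0.01, 0.005)
    edge_counts: tuple[int, ...] = (100, 500, 1000, 2000)
    n_nodes: int = 100
    p0: float = 0.3
    p1: float = 0.1
    train_draws_per_model: int = 10000
    test_networks_per_model: int = 1000
    subsamples_per_test: int = 100
    fraction: float = 0.8
    learner: str = "super"
    seed: int = 0
    scale: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.scale <= 1.0:
            raise ValueError("scale must lie in (0, 1]")

    def scaled(self, count: int) -> int:
        return max(1, int(round(count * self.scale)))


@dataclass
class CellResult:
    """One grid cell: accuracy plus per-test-network confidence records."""

    p_delta: float
    m: int
    proportion_correct: float
    records: pd.DataFrame  # true_model, selected, confidence_correct, correct

    @property
    def median_confidence_correct(self) -> float:
        return float(self.records["confidence_correct"].median())


def _cell_specs(cfg: SelectionStudyConfig, p_delta: float, m: int) -> tuple[ModelSpec, ModelSpec]:
    def spec(pd_):
        return ModelSpec(
            family="triangle_closure",
            n=cfg.n_nodes,
            m=m,
            params={"p0": cfg.p0, "p1": cfg.p1, "p_delta": pd_},
        )

    return spec(0.0), spec(p_delta)


def run_selection_cell(
    cfg: SelectionStudyConfig,
    p_delta: float,
    m: int,
    *,
    p_delta_null: float | None = None,
    seed: int | None = None,
) -> CellResult:
    """Train and evaluate one (p_delta, m) cell.

    Model 1 uses ``p_delta_null`` (default 0) and model 2 uses ``p_delta``;
    the test set holds equally many networks drawn from each.
    """
    spec1, spec2 = _cell_specs(cfg, p_delta, m)
    if p_delta_null is not None:
        spec1 = _cell_specs(cfg, p_delta_null, m)[1]
    base = np.random.SeedSequence(cfg.seed if seed is None else seed)
    ss_train1, ss_train2, ss_test, ss_learner = base.spawn(4)

    n_train = cfg.scaled(cfg.train_draws_per_model)
    n_test = cfg.scaled(cfg.test_networks_per_model)
    stats = SELECTION_STATS
    train_scheme = SubsampleScheme(
        fraction=cfg.fraction, b_obs=cfg.subsamples_per_test, b_model=n_train
    )

    blocks, labels = [], []
    for i, (spec, ss) in enumerate([(spec1, ss_train1), (spec2, ss_train2)]):
        dist = build_model_distribution(
            spec, stats, train_scheme.with_seed(int(ss.generate_state(1)[0])), "independent"
        )
        blocks.append(dist.values)
        labels.append(np.full(dist.n_rows, i))
    X = np.vstack(blocks)
    y = np.concatenate(labels)
    learner = build_learner(cfg.learner, int(ss_learner.generate_state(1)[0]))
    learner.fit(X, y)

    size = subsample_size(cfg.n_nodes, cfg.fraction)
    b_o = cfg.subsamples_per_test
    rows = []
    test_children = iter(ss_test.spawn(2 * n_test))
    for true_model, spec in [(0, spec1), (1, spec2)]:
        for _ in range(n_test):
            rng = np.random.default_rng(next(test_children))
            a = generate_adjacency(spec, rng).astype(float)
            feats = np.empty((b_o, len(stats)))
            for b in range(b_o):
                idx = rng.choice(cfg.n_nodes, size=size, replace=False)
                feats[b] = stat_row_from_adjacency(a[np.ix_(idx, idx)], stats)
            pred = learner.predict(feats)
            selected, _, _, _ = tally_assignments(pred, 2)
            rows.append(
                {
                    "true_model": true_model,
                    "selected": selected,
                    "confidence_correct": float(np.mean(pred == true_model)),
                    "correct": selected == true_model,
                }
            )
    records = pd.DataFrame(rows)
    return CellResult(
        p_delta=p_delta,
        m=m,
        proportion_correct=float(records["correct"].mean()),
        records=records,
    )


def run_selection_study(
    cfg: SelectionStudyConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every grid cell; returns (cell table, per-network records)."""
    base = np.random.SeedSequence(cfg.seed)
    cells = list(itertools.product(cfg.p_deltas, cfg.edge_counts))
    table_rows = []
    record_frames = []
    for (p_delta, m), child in zip(cells, base.spawn(len(cells))):
        cell = run_selection_cell(
            cfg, p_delta, m, seed=int(child.generate_state(1)[0])
        )
        table_rows.append(
            {
                "p_delta": p_delta,
                "m": m,
                "proportion_correct": cell.proportion_correct,
                "median_confidence_correct": cell.median_confidence_correct,
            }
        )
        rec = cell.records.copy()
        rec.insert(0, "p_delta", p_delta)
        rec.insert(1, "m", m)
        record_frames.append(rec)
    return pd.DataFrame(table_rows), pd.concat(record_frames, ignore_index=True)


# ---------------------------------------------------------------------------
# stability study


@dataclass(frozen=True)
class StabilityStudyConfig:
    """Sizes for the seed-stability study.

    ``models`` maps a label to (family, params) pairs; defaults are the
    study's ER growth with p = 0.1, DMC(q_mod=0.2, q_con=0.1) and
    DMR(q_del=0.2, q_new=0.1).
    """

    models: tuple[tuple[str, str, dict], ...] = (
        ("er_growth", "er_growth", {"p": 0.1}),
        ("dmc", "dmc", {"q_mod": 0.2, "q_con": 0.1}),
        ("dmr", "dmr", {"q_del": 0.2, "q_new": 0.1}),
    )
    n_values: tuple[int, ...] = (1000, 3000, 5000, 7000, 10000)
    seed_sizes: tuple[int, ...] = (5, 8, 10, 20, 50, 100)
    replicates: int = 50
    seed: int = 0
    scale: float = 1.0

    def scaled_replicates(self) -> int:
        return max(2, int(round(self.replicates * self.scale)))


def total_variation(deg_a: np.ndarray, deg_b: np.ndarray) -> float:
    """TV distance between two empirical degree distributions."""
    deg_a = np.asarray(deg_a, dtype=int)
    deg_b = np.asarray(deg_b, dtype=int)
    width = max(deg_a.max(initial=0), deg_b.max(initial=0)) + 1
    pa = np.bincount(deg_a, minlength=width) / deg_a.size
    pb = np.bincount(deg_b, minlength=width) / deg_b.size
    return float(0.5 * np.abs(pa - pb).sum())


def mean_pairwise_tv(degree_sequences: Sequence[np.ndarray]) -> float:
    """Mean TV distance over all unordered pairs of replicate degree sequences."""
    pairs = list(itertools.combinations(range(len(degree_sequences)), 2))
    if not pairs:
        raise ValueError("need at least 2 replicates")
    return float(
        np.mean(
            [
                total_variation(degree_sequences[i], degree_sequences[j])
                for i, j in pairs
            ]
        )
    )


def replicate_degree_sequences(
    family: str,
    params: dict,
    n: int,
    seed_size: int,
    replicates: int,
    seed: int | None = None,
) -> list[np.ndarray]:
    """Degree sequences of ``replicates`` independent draws from one model."""
    spec = ModelSpec(
        family=family, n=n, seed=SeedSpec(kind="complete", k=seed_size), params=params
    )
    out = []
    for child in np.random.SeedSequence(seed).spawn(replicates):
        a = generate_adjacency(spec, np.random.default_rng(child))
        out.append(a.sum(axis=1).astype(int))
    return out


def run_stability_study(cfg: StabilityStudyConfig) -> pd.DataFrame:
    """Mean pairwise TV of replicate degree distributions per (model, n, seed size)."""
    base = np.random.SeedSequence(cfg.seed)
    combos = list(itertools.product(cfg.models, cfg.n_values, cfg.seed_sizes))
    rows = []
    reps = cfg.scaled_replicates()
    for ((label, family, params), n, k), child in zip(combos, base.spawn(len(combos))):
        seqs = replicate_degree_sequences(
            family, params, n, k, reps, int(child.generate_state(1)[0])
        )
        rows.append(
            {
                "model": label,
                "n": n,
                "seed_size": k,
                "replicates": reps,
                "mean_pairwise_tv": mean_pairwise_tv(seqs),
            }
        )
    return pd.DataFrame(rows)


def plot_confidence_histograms(records: pd.DataFrame, path: str) -> None:
    """Histogram grid of confidence in the correct model, one panel per cell."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p_deltas = sorted(records["p_delta"].unique(), reverse=True)
    ms = sorted(records["m"].unique())
    fig, axes = plt.subplots(
        len(ms), len(p_deltas), figsize=(3 * len(p_deltas), 2.2 * len(ms)), squeeze=False
    )
    for r, m in enumerate(ms):
        for c, pd_ in enumerate(p_deltas):
            ax = axes[r][c]
            sel = records[(records["m"] == m) & (records["p_delta"] == pd_)]
            conf = sel["confidence_correct"]
            ax.hist(conf, bins=np.linspace(0, 1, 21), color="steelblue")
            if len(conf):
                ax.axvline(conf.median(), color="red")
            ax.set_title(f"p_delta={pd_}, m={m}", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
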