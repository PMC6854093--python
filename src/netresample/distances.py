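"""Distances between resampling distributions.

Two one-dimensional measures are provided: the two-sample
Kolmogorov-Smirnov statistic (the supremum absolute difference between the
two empirical CDFs, well defined for discrete data with ties) and a binned
Kullback-Leibler divergence.  Both operate column-wise on
:class:`~netresample.resampling.ResamplingDistribution` objects via
:func:`distance_profile`.

The measures are used descriptively, to order candidate models by fit; no
p-values are attached (the subsample rows are dependent, so the usual KS
null distribution would not apply anyway).

Multidimensional generalisations are deliberately not shipped; callers who
want a joint comparison across statistics can pass any callable on the two
raw B x |S| matrices to :func:`joint_distance`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import rel_entr

__all__ = [
    "DistanceProfile",
    "ks_statistic",
    "kl_divergence",
    "distance_profile",
    "joint_distance",
]

MEASURES = ("ks", "kl")


def _as_sample(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError(f"{name} sample is empty")
    return x


def ks_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sample KS statistic: sup_t |ECDF_x(t) - ECDF_y(t)|.

    Evaluated over the pooled sample points with right-continuous ECDFs, so
    ties and discrete supports are handled exactly.  Symmetric, in [0, 1].
    """
    x = np.sort(_as_sample(x, "first"))
    y = np.sort(_as_sample(y, "second"))
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / x.size
    cdf_y = np.searchsorted(y, pooled, side="right") / y.size
    return float(np.max(np.abs(cdf_x - cdf_y)))


def kl_divergence(
    x: Sequence[float],
    y: Sequence[float],
    bins: int | str | Sequence[float] = "fd",
    smoothing: float | None = None,
) -> float:
    """Binned KL divergence KL(P_x || P_y) in nats.

    Both samples are histogrammed on shared bins (Freedman-Diaconis on the
    pooled sample by default).  ``smoothing`` mass is added to every bin
    before normalising -- by default ``1 / (2 * (len(x) + len(y)))`` -- so
    empty bins never produce infinities; pass ``smoothing=0`` for the raw
    plug-in estimate.  Asymmetric by definition.
    """
    x = _as_sample(x, "first")
    y = _as_sample(y, "second")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        edges = np.array([pooled[0] - 0.5, pooled[0] + 0.5])
    else:
        edges = np.histogram_bin_edges(pooled, bins=bins)
    hx = np.histogram(x, bins=edges)[0].astype(float)
    hy = np.histogram(y, bins=edges)[0].astype(float)
    if smoothing is None:
        smoothing = 1.0 / (2.0 * (x.size + y.size))
    hx += smoothing
    hy += smoothing
    px = hx / hx.sum()
    py = hy / hy.sum()
    return float(rel_entr(px, py).sum())


@dataclass(frozen=True)
class DistanceProfile:
    """Per-statistic distances between two resampling distributions."""

    stat_names: tuple[str, ...]
    values: np.ndarray
    measure: str
    n_x: int
    n_y: int

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.stat_names, np.asarray(self.values).tolist()))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.stat_names.index(name)])


def _measure_fn(measure: str, **kwargs) -> Callable[[np.ndarray, np.ndarray], float]:
    if measure == "ks":
        return ks_statistic
    if measure == "kl":
        return lambda x, y: kl_divergence(x, y, **kwargs)
    raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")


def distance_profile(a, b, measure: str = "ks", **kwargs) -> DistanceProfile:
    """Column-wise distance between two resampling distributions.

    ``a`` and ``b`` must carry identical statistic names in identical order.
    """
    if tuple(a.stat_names) != tuple(b.stat_names):
        only_a = set(a.stat_names) - set(b.stat_names)
        only_b = set(b.stat_names) - set(a.stat_names)
        raise ValueError(
            "statistic mismatch between distributions: "
            f"only in first: {sorted(only_a)}; only in second: {sorted(only_b)}; "
            f"orders: {a.stat_names} vs {b.stat_names}"
        )
    fn = _measure_fn(measure, **kwargs)
    values = np.array(
        [fn(a.values[:, k], b.values[:, k]) for k in range(len(a.stat_names))]
    )
    return DistanceProfile(tuple(a.stat_names), values, measure, a.n_rows, b.n_rows)


def joint_distance(a, b, fn: Callable[[np.ndarray, np.ndarray], float]) -> float:
    """Extension hook: apply a user multivariate distance to the raw matrices.

    ``fn`` receives the two B x |S| value matrices (identical column order
    is checked) and returns a scalar; the package itself ships no specific
    multidimensional KS/KL generalisation.
    """
    if tuple(a.stat_names) != tuple(b.stat_names):
        raise ValueError("statistic mismatch between distributions")
    return float(fn(a.values, b.values))
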