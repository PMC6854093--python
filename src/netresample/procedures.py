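"""Statistical procedures on resampling distributions.

Three use cases are implemented on top of the subsampling machinery:

* :func:`assess_gof` -- goodness of fit: build ``F_o`` from the observed
  network and one ``F_c`` per candidate model, then report per-statistic
  distances and the induced orderings of the candidates.
* :class:`ModelSelector` / :func:`fit_selector` / :func:`select_model` --
  model selection: train a classifier on labelled subsample statistics from
  each candidate model, classify every subsample of the observed network,
  and select by plurality; the winning proportion is the confidence.
* :func:`compare_networks` -- pairwise distances between the resampling
  distributions of several observed networks.

``ModelSelector`` follows the scikit-learn estimator contract
(``get_params`` / ``set_params``, ``fit``, ``predict``, fitted attributes
with trailing underscores) so it composes with sklearn tooling; ``fit``
generates its own training table from the candidate model specs, and
``predict`` accepts a plain feature matrix of subsample statistics.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier, StackingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import NuSVC

from .distances import DistanceProfile, distance_profile
from .generators import ModelSpec
from .graph import DEFAULT_GOF_STATS, SELECTION_STATS
from .resampling import (
    ResamplingDistribution,
    SubsampleScheme,
    build_model_distribution,
    build_observed_distribution,
)

__all__ = [
    "GofReport",
    "SelectionResult",
    "NetworkComparison",
    "ModelSelector",
    "build_learner",
    "fit_selector",
    "select_model",
    "assess_gof",
    "compare_networks",
    "tally_assignments",
]

LEARNERS = ("svm", "rf", "knn", "super")


def build_learner(learner: str | BaseEstimator = "super", random_state: int | None = None):
    """Construct one of the reference classifiers, or clone a user estimator.

    ``svm`` is a nu-SVC (nu = 0.5, radial kernel) behind a standardiser,
    ``rf`` a 1000-tree random forest with minimum terminal node size 1,
    ``knn`` k-nearest neighbours with k = 10, and ``super`` stacks all
    three with a cross-validated logistic meta-learner (the ensemble role).
    Any object with ``fit``/``predict`` may be passed instead.
    """
    if not isinstance(learner, str):
        return clone(learner)

    def svm():
        return make_pipeline(StandardScaler(), NuSVC(nu=0.5, kernel="rbf"))

    def rf():
        return RandomForestClassifier(
            n_estimators=1000, min_samples_leaf=1, random_state=random_state
        )

    def knn():
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=10))

    if learner == "svm":
        return svm()
    if learner == "rf":
        return rf()
    if learner == "knn":
        return knn()
    if learner == "super":
        return StackingClassifier(
            estimators=[("svm", svm()), ("rf", rf()), ("knn", knn())],
            final_estimator=LogisticRegression(max_iter=1000),
            cv=5,
        )
    raise ValueError(f"unknown learner {learner!r}; expected one of {LEARNERS}")


def _spec_stream_seed(spec: ModelSpec, base_seed: int | None) -> int:
    """Stable RNG seed for a candidate, independent of its list position."""
    digest = hashlib.sha256(
        json.dumps(spec.to_dict(), sort_keys=True).encode()
    ).digest()
    spec_key = int.from_bytes(digest[:4], "big")
    mix = np.random.SeedSequence(
        entropy=0 if base_seed is None else base_seed, spawn_key=(spec_key,)
    )
    return int(mix.generate_state(1)[0])


def tally_assignments(labels: Sequence[int], n_models: int) -> tuple[int, np.ndarray, float, bool]:
    """Plurality vote over per-subsample model assignments.

    Returns ``(selected, proportions, confidence, tie)``; ties are broken by
    the lowest model index and flagged.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("no assignments to tally")
    counts = np.bincount(labels, minlength=n_models).astype(float)
    proportions = counts / counts.sum()
    best = float(proportions.max())
    winners = np.flatnonzero(proportions == best)
    return int(winners[0]), proportions, best, winners.size > 1


@dataclass
class SelectionResult:
    """Outcome of plurality model selection for one observed network."""

    selected: int
    assignments: np.ndarray
    proportions: np.ndarray
    confidence: float
    tie: bool
    learner: str
    model_descriptions: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "confidence": self.confidence,
            "tie": self.tie,
            "proportions": np.asarray(self.proportions).tolist(),
            "assignments": np.asarray(self.assignments).tolist(),
            "learner": self.learner,
            "models": list(self.model_descriptions),
        }


class ModelSelector(ClassifierMixin, BaseEstimator):
    """Classifier-based model selection over candidate network models.

    Parameters
    ----------
    candidates:
        Sequence of :class:`~netresample.generators.ModelSpec`; class label
        ``i`` means "drawn from ``candidates[i]``".
    stats:
        Statistic identifiers used as predictors (default: average local
        clustering, triangle count and the three degree quartiles).
    scheme:
        Subsampling design.  Training uses ``scheme.b_model`` independent
        draws per candidate with one subsample each; selection classifies
        ``scheme.b_obs`` subsamples of the observed network.
    learner:
        Name from :data:`LEARNERS` or a scikit-learn estimator.
    random_state:
        Master seed for training-data generation and the learner.
    """

    def __init__(
        self,
        candidates: Sequence[ModelSpec] = (),
        stats: Sequence[str] = SELECTION_STATS,
        scheme: SubsampleScheme | None = None,
        learner: str | BaseEstimator = "super",
        random_state: int | None = None,
    ):
        self.candidates = candidates
        self.stats = stats
        self.scheme = scheme
        self.learner = learner
        self.random_state = random_state

    def _resolved_scheme(self) -> SubsampleScheme:
        return self.scheme if self.scheme is not None else SubsampleScheme()

    def fit(self, X=None, y=None) -> "ModelSelector":
        """Build the labelled training table and fit the learner.

        With ``X``/``y`` given, fits directly on that feature matrix
        (feature-space mode, for sklearn interoperability); otherwise the
        table is generated from ``candidates``: ``scheme.b_model`` rows of
        subsample statistics per candidate, labelled by candidate index.
        """
        scheme = self._resolved_scheme()
        if X is None:
            if len(self.candidates) < 2:
                raise ValueError("model selection requires at least 2 candidates")
            blocks, labels = [], []
            for i, spec in enumerate(self.candidates):
                sc = scheme.with_seed(_spec_stream_seed(spec, self.random_state))
                dist = build_model_distribution(spec, self.stats, sc, "independent")
                if dist.n_rows == 0:
                    raise ValueError(
                        f"candidate {i} produced no finite training rows"
                    )
                blocks.append(dist.values)
                labels.append(np.full(dist.n_rows, i))
            X = np.vstack(blocks)
            y = np.concatenate(labels)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("training table is single-class; cannot select")
        self.learner_ = build_learner(self.learner, self.random_state)
        self.learner_.fit(X, y)
        self.X_ = X
        self.y_ = y
        self.classes_ = self.learner_.classes_
        self.n_features_in_ = X.shape[1]
        self.stat_names_ = tuple(self.stats)
        self.scheme_ = scheme
        return self

    def predict(self, X) -> np.ndarray:
        """Predict candidate indices for rows of subsample statistics."""
        return self.learner_.predict(np.asarray(X, dtype=float))

    def predict_subsamples(self, g: nx.Graph | np.ndarray) -> np.ndarray:
        """Classify each of ``scheme.b_obs`` subsamples of one network."""
        f_o = build_observed_distribution(g, self.stat_names_, self.scheme_)
        if f_o.n_rows == 0:
            raise ValueError("all observed subsamples had undefined statistics")
        return self.predict(f_o.values)

    def select(self, g: nx.Graph | np.ndarray) -> SelectionResult:
        """Plurality selection with confidence for one observed network."""
        labels = self.predict_subsamples(g)
        n_models = max(len(self.candidates), int(np.max(self.classes_)) + 1)
        selected, proportions, confidence, tie = tally_assignments(labels, n_models)
        return SelectionResult(
            selected=selected,
            assignments=labels,
            proportions=proportions,
            confidence=confidence,
            tie=tie,
            learner=str(self.learner),
            model_descriptions=tuple(
                f"{s.family}(n={s.n})" for s in self.candidates
            ),
        )


def fit_selector(
    candidates: Sequence[ModelSpec],
    stats: Sequence[str] = SELECTION_STATS,
    scheme: SubsampleScheme | None = None,
    learner: str | BaseEstimator = "super",
    rng: int | None = None,
) -> ModelSelector:
    """Train a :class:`ModelSelector` on the candidate models."""
    return ModelSelector(
        candidates=list(candidates),
        stats=tuple(stats),
        scheme=scheme,
        learner=learner,
        random_state=rng,
    ).fit()


def select_model(selector: ModelSelector, g_obs: nx.Graph | np.ndarray) -> SelectionResult:
    """Apply a trained selector to an observed network."""
    return selector.select(g_obs)


# ---------------------------------------------------------------------------
# goodness of fit


@dataclass
class GofReport:
    """Per-model distance profiles with induced orderings and summaries."""

    model_descriptions: tuple[str, ...]
    model_specs: tuple[dict, ...]
    stat_names: tuple[str, ...]
    measures: tuple[str, ...]
    profiles: dict  # measure -> list[DistanceProfile], one per model
    orderings: dict  # measure -> {stat -> list of model indices, best first}
    observed_summary: pd.DataFrame
    model_summaries: tuple[pd.DataFrame, ...]
    scheme: SubsampleScheme
    degenerate_models: tuple[int, ...] = ()

    def distances_frame(self, measure: str) -> pd.DataFrame:
        rows = {
            desc: prof.as_dict()
            for desc, prof in zip(self.model_descriptions, self.profiles[measure])
        }
        return pd.DataFrame(rows).T[list(self.stat_names)]

    def to_dict(self) -> dict:
        return {
            "models": list(self.model_descriptions),
            "model_specs": list(self.model_specs),
            "stats": list(self.stat_names),
            "measures": list(self.measures),
            "scheme": {
                "fraction": self.scheme.fraction,
                "b_obs": self.scheme.b_obs,
                "b_model": self.scheme.b_model,
                "seed": self.scheme.seed,
            },
            "distances": {
                m: [p.as_dict() for p in self.profiles[m]] for m in self.measures
            },
            "orderings": {
                m: {s: list(v) for s, v in self.orderings[m].items()}
                for m in self.measures
            },
            "observed_summary": self.observed_summary.to_dict(),
            "model_summaries": [s.to_dict() for s in self.model_summaries],
            "degenerate_models": list(self.degenerate_models),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_tsv(self, path: str | Path) -> None:
        frames = []
        for m in self.measures:
            f = self.distances_frame(m)
            f.insert(0, "measure", m)
            frames.append(f)
        pd.concat(frames).to_csv(path, sep="\t", index_label="model")


def assess_gof(
    g_obs: nx.Graph | np.ndarray,
    candidates: Sequence[ModelSpec],
    stats: Sequence[str] = DEFAULT_GOF_STATS,
    scheme: SubsampleScheme | None = None,
    measures: Sequence[str] = ("ks",),
) -> GofReport:
    """Assess the fit of each candidate model to one observed network.

    Builds ``F_o`` once and one independent-draw ``F_c`` per candidate (all
    at the same subsample fraction), then reports per-statistic distances
    under each measure together with the orderings they induce.  Orderings
    are reported per statistic and never collapsed into a single overall
    rank, since different statistics can legitimately disagree about which
    model fits best.
    """
    scheme = scheme if scheme is not None else SubsampleScheme()
    names = tuple(stats)
    n_obs = (
        g_obs.shape[0] if isinstance(g_obs, np.ndarray) else g_obs.number_of_nodes()
    )
    for i, spec in enumerate(candidates):
        if spec.n != n_obs:
            warnings.warn(
                f"candidate {i} has n={spec.n} but the observed network has "
                f"{n_obs} nodes; resampling distributions are not comparable",
                stacklevel=2,
            )
    f_o = build_observed_distribution(g_obs, names, scheme)
    if f_o.n_rows == 0:
        raise ValueError("observed network produced no finite subsample rows")
    f_cs = []
    degenerate = []
    for i, spec in enumerate(candidates):
        sc = scheme.with_seed(_spec_stream_seed(spec, scheme.seed))
        f_c = build_model_distribution(spec, names, sc, "independent")
        if f_c.n_rows == 0:
            degenerate.append(i)
        f_cs.append(f_c)

    measures = tuple(measures)
    profiles: dict[str, list[DistanceProfile]] = {}
    orderings: dict[str, dict[str, list[int]]] = {}
    for m in measures:
        profs = []
        for i, f_c in enumerate(f_cs):
            if i in degenerate:
                profs.append(
                    DistanceProfile(
                        names, np.full(len(names), np.nan), m, f_o.n_rows, 0
                    )
                )
            else:
                profs.append(distance_profile(f_o, f_c, m))
        profiles[m] = profs
        orderings[m] = {
            s: sorted(
                (i for i in range(len(candidates)) if i not in degenerate),
                key=lambda i: (profs[i][s], i),
            )
            for s in names
        }
    return GofReport(
        model_descriptions=tuple(
            f"{s.family}(n={s.n})#{i}" for i, s in enumerate(candidates)
        ),
        model_specs=tuple(s.to_dict() for s in candidates),
        stat_names=names,
        measures=measures,
        profiles=profiles,
        orderings=orderings,
        observed_summary=f_o.summary(),
        model_summaries=tuple(f.summary() for f in f_cs),
        scheme=scheme,
        degenerate_models=tuple(degenerate),
    )


# ---------------------------------------------------------------------------
# multi-network comparison


@dataclass
class NetworkComparison:
    """Pairwise distances between observed networks' resampling distributions."""

    labels: tuple[str, ...]
    stat_names: tuple[str, ...]
    per_stat: dict  # stat -> k x k matrix
    aggregate: np.ndarray  # mean over statistics
    measure: str

    def frame(self, stat: str | None = None) -> pd.DataFrame:
        mat = self.aggregate if stat is None else self.per_stat[stat]
        return pd.DataFrame(mat, index=list(self.labels), columns=list(self.labels))


def compare_networks(
    graphs: Sequence[nx.Graph | np.ndarray],
    stats: Sequence[str] = DEFAULT_GOF_STATS,
    scheme: SubsampleScheme | None = None,
    measure: str = "ks",
    labels: Sequence[str] | None = None,
) -> NetworkComparison:
    """All pairwise distances between the networks' resampling distributions.

    Each network gets its own observed-side distribution (``scheme.b_obs``
    subsamples at ``scheme.fraction``); entry (i, j) is the per-statistic
    distance between distributions i and j.  With the KS measure the
    matrices are exactly symmetric.
    """
    if len(graphs) < 2:
        raise ValueError("network comparison requires at least 2 graphs")
    scheme = scheme if scheme is not None else SubsampleScheme()
    names = tuple(stats)
    labels = (
        tuple(labels)
        if labels is not None
        else tuple(f"network_{i}" for i in range(len(graphs)))
    )
    base = np.random.SeedSequence(scheme.seed)
    dists = [
        build_observed_distribution(
            g,
            names,
            scheme.with_seed(int(child.generate_state(1)[0])),
            source=lab,
        )
        for g, lab, child in zip(graphs, labels, base.spawn(len(graphs)))
    ]
    k = len(graphs)
    per_stat = {s: np.zeros((k, k)) for s in names}
    for i in range(k):
        for j in range(i + 1, k):
            prof = distance_profile(dists[i], dists[j], measure)
            for s in names:
                per_stat[s][i, j] = per_stat[s][j, i] = prof[s]
    aggregate = np.mean([per_stat[s] for s in names], axis=0)
    return NetworkComparison(labels, names, per_stat, aggregate, measure)
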