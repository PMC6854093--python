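"""Goodness of fit, model selection and multi-network comparison."""

import numpy as np
import pytest
from sklearn.base import clone

from netresample.generators import ModelSpec, SeedSpec, generate
from netresample.procedures import (
    ModelSelector,
    assess_gof,
    compare_networks,
    fit_selector,
    select_model,
    tally_assignments,
)
from netresample.resampling import SubsampleScheme


def er_spec(n, p, k=5):
    return ModelSpec("er_growth", n=n, seed=SeedSpec("complete", k=k), params={"p": p})


def dmc_spec(n, q_mod=0.2, q_con=0.1, k=10):
    return ModelSpec(
        "dmc", n=n, seed=SeedSpec("complete", k=k), params={"q_mod": q_mod, "q_con": q_con}
    )


# ---------------------------------------------------------------------------
# tallying


def test_tally_majority():
    sel, props, conf, tie = tally_assignments([1, 1, 0, 1, 1], 2)
    assert sel == 1 and conf == 0.8 and not tie
    np.testing.assert_allclose(props, [0.2, 0.8])
    assert props.sum() == 1.0


def test_tally_unanimous_and_tie():
    sel, _, conf, tie = tally_assignments([0] * 10, 2)
    assert sel == 0 and conf == 1.0 and not tie
    sel, _, conf, tie = tally_assignments([0, 1] * 25, 2)
    assert tie and sel == 0 and conf == 0.5
    with pytest.raises(ValueError):
        tally_assignments([], 2)


def test_tally_plurality_three_models():
    sel, props, conf, tie = tally_assignments([0, 1, 1, 2, 1], 3)
    assert sel == 1 and conf == 0.6 and not tie
    assert props.shape == (3,)


# ---------------------------------------------------------------------------
# goodness of fit


def test_gof_verbatim_candidate_ranks_first():
    # a degenerate 'model' that replays the observed network on every draw
    # (growth from an explicit seed with zero steps) must fit best
    g_obs = generate(er_spec(40, 0.15), 7)
    replay = ModelSpec(
        "er_growth", n=40, seed=SeedSpec("explicit", graph=g_obs), params={"p": 0.5}
    )
    dense = er_spec(40, 0.6)
    scheme = SubsampleScheme(fraction=0.5, b_obs=60, b_model=60, seed=1)
    stats = ("avg_clustering", "triangles")
    report = assess_gof(g_obs, [dense, replay], stats, scheme)
    for s in stats:
        d_replay = report.profiles["ks"][1][s]
        d_dense = report.profiles["ks"][0][s]
        assert d_replay < d_dense
        assert report.orderings["ks"][s][0] == 1


def test_gof_ordering_invariant_to_candidate_order():
    g_obs = generate(er_spec(50, 0.1), 3)
    cands = [er_spec(50, 0.05), er_spec(50, 0.1), er_spec(50, 0.3)]
    scheme = SubsampleScheme(fraction=0.5, b_obs=40, b_model=40, seed=5)
    stats = ("triangles", "avg_clustering")
    r1 = assess_gof(g_obs, cands, stats, scheme)
    r2 = assess_gof(g_obs, list(reversed(cands)), stats, scheme)
    for s in stats:
        # map index ordering back to specs: must be identical
        o1 = [cands[i].params["p"] for i in r1.orderings["ks"][s]]
        o2 = [list(reversed(cands))[i].params["p"] for i in r2.orderings["ks"][s]]
        assert o1 == o2
        d1 = sorted(p[s] for p in r1.profiles["ks"])
        d2 = sorted(p[s] for p in r2.profiles["ks"])
        np.testing.assert_allclose(d1, d2)


def test_gof_report_contents_and_serialization(tmp_path):
    g_obs = generate(er_spec(40, 0.1), 11)
    cands = [er_spec(40, 0.1), er_spec(40, 0.5)]
    scheme = SubsampleScheme(fraction=0.5, b_obs=30, b_model=30, seed=2)
    report = assess_gof(
        g_obs, cands, ("triangles", "avg_clustering"), scheme, measures=("ks", "kl")
    )
    frame = report.distances_frame("ks")
    assert frame.shape == (2, 2)
    assert set(report.measures) == {"ks", "kl"}
    # mismatched size warning
    with pytest.warns(UserWarning, match="not comparable"):
        assess_gof(g_obs, [er_spec(30, 0.1)], ("triangles",), scheme)
    report.to_json(tmp_path / "gof.json")
    report.to_tsv(tmp_path / "gof.tsv")
    assert (tmp_path / "gof.json").stat().st_size > 0
    import json

    payload = json.loads((tmp_path / "gof.json").read_text())
    assert payload["scheme"]["seed"] == 2
    assert len(payload["distances"]["ks"]) == 2


# ---------------------------------------------------------------------------
# model selection


def test_fit_selector_separable_training():
    sparse, dense = er_spec(60, 0.02), er_spec(60, 0.5)
    scheme = SubsampleScheme(fraction=0.5, b_obs=50, b_model=60, seed=4)
    selector = fit_selector([sparse, dense], ("triangles", "deg_q50"), scheme, "knn", rng=0)
    assert selector.X_.shape == (120, 2)
    assert selector.y_.shape == (120,)
    # non-overlapping triangle supports: training accuracy 1
    assert (selector.predict(selector.X_) == selector.y_).mean() == 1.0


def test_select_model_recovers_generator():
    sparse, dense = er_spec(60, 0.02), er_spec(60, 0.5)
    scheme = SubsampleScheme(fraction=0.5, b_obs=50, b_model=60, seed=4)
    selector = fit_selector([sparse, dense], ("triangles", "deg_q50"), scheme, "knn", rng=0)
    g_obs = generate(dense, 123)
    result = select_model(selector, g_obs)
    assert result.selected == 1
    assert result.confidence > 0.9
    assert result.proportions.sum() == pytest.approx(1.0)
    assert result.confidence == result.proportions.max()
    assert len(result.assignments) == 50
    payload = result.to_dict()
    assert payload["selected"] == 1 and len(payload["proportions"]) == 2


def test_selector_deterministic_given_random_state():
    cands = [er_spec(50, 0.05), er_spec(50, 0.4)]
    scheme = SubsampleScheme(fraction=0.4, b_obs=30, b_model=40, seed=8)
    g_obs = generate(cands[0], 77)
    r1 = fit_selector(cands, ("triangles", "avg_clustering"), scheme, "rf", rng=1).select(g_obs)
    r2 = fit_selector(cands, ("triangles", "avg_clustering"), scheme, "rf", rng=1).select(g_obs)
    np.testing.assert_array_equal(r1.assignments, r2.assignments)
    assert r1.confidence == r2.confidence


def test_selector_sklearn_contract():
    selector = ModelSelector(candidates=[er_spec(20, 0.1)], learner="knn", random_state=3)
    params = selector.get_params()
    assert params["learner"] == "knn"
    cloned = clone(selector)
    assert cloned.get_params()["random_state"] == 3
    cloned.set_params(learner="svm")
    assert cloned.learner == "svm"
    # feature-space mode: fit directly on arrays like any sklearn classifier
    X = np.vstack([np.zeros((20, 2)), np.ones((20, 2))])
    y = np.repeat([0, 1], 20)
    fitted = ModelSelector(learner="knn").fit(X, y)
    assert (fitted.predict(X) == y).all()
    with pytest.raises(ValueError, match="single-class"):
        ModelSelector(learner="knn").fit(X, np.zeros(40))
    with pytest.raises(ValueError, match="at least 2"):
        ModelSelector(candidates=[er_spec(20, 0.1)], learner="knn").fit()


# ---------------------------------------------------------------------------
# multi-network comparison


def test_compare_networks_symmetry_and_duplicates():
    g1 = generate(er_spec(60, 0.1), 1)
    g2 = generate(dmc_spec(60), 2)
    scheme = SubsampleScheme(fraction=0.4, b_obs=80, seed=6)
    comp = compare_networks(
        [g1, g2, g1], ("triangles", "avg_clustering"), scheme, "ks"
    )
    assert comp.aggregate.shape == (3, 3)
    assert len(comp.per_stat) == 2
    for mat in comp.per_stat.values():
        np.testing.assert_array_equal(mat, mat.T)
        assert np.all(np.diag(mat) == 0)
    # same graph twice: only subsample noise separates entries (0, 2)
    assert comp.aggregate[0, 2] < 0.25
    # clearly different generators are far apart
    assert comp.per_stat["triangles"][0, 1] > comp.per_stat["triangles"][0, 2]
    with pytest.raises(ValueError, match="at least 2"):
        compare_networks([g1], ("triangles",), scheme)
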