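"""Sparse PLS-DA: selection, projection, dense oracle, robustness."""

import numpy as np
import pandas as pd
import pytest

from methsub.splsda import (fit_splsda, project, randomization_robustness,
                            robustness_trend, selected_features)


def dense_pls_oracle(X, y, ncomp):
    """Brute-force dense PLS-DA scores via SVD of X'Y with deflation."""
    Xd = (X - X.mean(0)) / X.std(0, ddof=1)
    levels = np.unique(y)
    Y = np.zeros((len(y), len(levels)))
    for i, lev in enumerate(levels):
        Y[y == lev, i] = 1.0
    Yd = Y - Y.mean(0)
    T = []
    for _ in range(ncomp):
        U, S, Vt = np.linalg.svd(Xd.T @ Yd, full_matrices=False)
        w = U[:, 0]
        j = int(np.argmax(np.abs(w)))
        w = w * np.sign(w[j])
        t = Xd @ w
        c = Xd.T @ t / (t @ t)
        d = Yd.T @ t / (t @ t)
        Xd = Xd - np.outer(t, c)
        Yd = Yd - np.outer(t, d)
        T.append(t)
    return np.column_stack(T)


def test_dense_limit_matches_oracle_on_small_matrices(rng):
    for trial in range(5):
        X = rng.normal(0, 1, (10, 8))
        y = np.repeat([0, 1], 5)
        model = fit_splsda(X, y, n_components=3, keep_per_component=8)
        T = dense_pls_oracle(X, y, 3)
        np.testing.assert_allclose(model.scores, T, atol=1e-8)


def test_single_discriminative_feature_selected(rng):
    X = rng.normal(0, 1, (40, 12))
    y = np.repeat([0, 1], 20)
    X[y == 1, 7] += 5.0  # feature 7 is the best single-feature discriminant
    model = fit_splsda(X, y, n_components=1, keep_per_component=1)
    per_comp, union = selected_features(model)
    assert union == {"f7"}


def test_selected_feature_counting(rng):
    X = rng.normal(0, 1, (30, 50))
    y = np.repeat([0, 1, 2], 10)
    model = fit_splsda(X, y, n_components=4, keep_per_component=5)
    per_comp, union = selected_features(model)
    assert all(len(s) == 5 for s in per_comp)
    assert len(union) <= 4 * 5
    one = fit_splsda(X, y, n_components=1, keep_per_component=5)
    pc1, u1 = selected_features(one)
    assert u1 == pc1[0]


def test_loading_weights_sparse_and_unit_norm(rng):
    X = rng.normal(0, 1, (25, 40))
    y = np.repeat([0, 1], [12, 13])
    model = fit_splsda(X, y, n_components=3, keep_per_component=6)
    for a in range(3):
        w = model.loading_weights[:, a]
        assert (w != 0).sum() == 6
        assert np.linalg.norm(w) == pytest.approx(1.0)


def test_scores_pairwise_uncorrelated(rng):
    X = rng.normal(0, 1, (50, 30))
    y = np.repeat([0, 1], 25)
    model = fit_splsda(X, y, n_components=4, keep_per_component=10)
    C = np.corrcoef(model.scores.T)
    off = C[np.triu_indices(4, 1)]
    assert np.abs(off).max() < 1e-6


def test_feature_scaling_invariance(rng):
    X = rng.normal(0, 1, (30, 20))
    y = np.repeat([0, 1], 15)
    a = fit_splsda(X, y, n_components=2, keep_per_component=5)
    X2 = X.copy()
    X2[:, 3] *= 17.0
    b = fit_splsda(X2, y, n_components=2, keep_per_component=5)
    assert selected_features(a)[1] == selected_features(b)[1]


def test_self_projection_and_duplicated_sample(rng):
    X = pd.DataFrame(rng.normal(0, 1, (20, 15)),
                     columns=[f"f{i}" for i in range(15)])
    y = np.repeat([0, 1], 10)
    model = fit_splsda(X, y, n_components=2, keep_per_component=10)
    np.testing.assert_allclose(project(model, X), model.scores, atol=1e-10)
    dup = pd.concat([X.iloc[[4]], X.iloc[[4]]])
    scores = project(model, dup)
    np.testing.assert_allclose(scores[0], scores[1])


def test_projection_requires_half_the_selection(rng):
    X = pd.DataFrame(rng.normal(0, 1, (20, 10)),
                     columns=[f"f{i}" for i in range(10)])
    y = np.repeat([0, 1], 10)
    model = fit_splsda(X, y, n_components=1, keep_per_component=10)
    with pytest.raises(ValueError, match="selected features shared"):
        project(model, X[[c for c in X.columns[:3]]])


def test_classes_with_too_few_samples_rejected(rng):
    X = rng.normal(0, 1, (5, 6))
    with pytest.raises(ValueError, match="fewer than 2"):
        fit_splsda(X, np.array([0, 0, 0, 0, 1]), n_components=1,
                   keep_per_component=3)


def test_masked_cohort_projection_keeps_subtypes_separated(small_study):
    """450K-masked cohort projected into an EPIC-trained latent space."""
    from sklearn.metrics import silhouette_score
    from methsub.preprocess import residualize
    ann = small_study.annotations.set_index("sample_id")
    cohorts = sorted(small_study.beta_by_cohort)
    disc = small_study.beta_by_cohort[cohorts[0]]
    rep = small_study.beta_by_cohort[cohorts[-1]]  # masked platform
    shared = disc.probe_ids.intersection(rep.probe_ids)

    def load_matrix(bm):
        load = [s for s in bm.sample_ids if ann.loc[s, "diagnosis"] == "LOAD"]
        r = residualize(bm, ann.loc[list(bm.sample_ids),
                                    ["age", "sex", "prop_neuron", "batch"]])
        return r.values.loc[shared, load].T, ann.loc[load, "truth"].to_numpy()

    Xd, yd = load_matrix(disc)
    Xr, yr = load_matrix(rep)
    model = fit_splsda(Xd, yd, n_components=2, keep_per_component=150)
    scores = project(model, Xr)
    assert silhouette_score(scores, yr) > 0.2


def test_robustness_identity_trend_and_determinism(rng):
    X = rng.normal(0, 1, (60, 120))
    y = np.repeat([0, 1], 30)
    X[y == 1, :30] += 1.2
    curve = randomization_robustness(
        X, y, n_components=2, keep_per_component=20,
        proportions=(1.0, 0.5, 0.25, 0.1, 0.0), n_repeats=4, seed=2)
    assert np.allclose(curve.overlap_fraction[:, -1], 1.0)  # p = 0 identity
    curve2 = randomization_robustness(
        X, y, n_components=2, keep_per_component=20,
        proportions=(1.0, 0.5, 0.25, 0.1, 0.0), n_repeats=4, seed=2)
    np.testing.assert_array_equal(curve.overlap_fraction, curve2.overlap_fraction)
    rho, p = robustness_trend(curve)
    assert rho < 0 and p < 0.05
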