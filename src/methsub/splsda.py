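"""Sparse partial least squares discriminant analysis (sPLS-DA).

Supervised projection with per-component feature sparsity: class labels are
dummy-coded, features centered and scaled, and each latent component's
weight vector is the dominant direction of X'Y Y'X (power iteration),
soft-thresholded to keep a fixed number of features, with X deflated by
regression on the component scores.  New cohorts are projected with the
regression-form rotation so self-projection reproduces training scores.

Also implements the label-randomization robustness procedure: labels of a
growing fraction of samples are permuted, the model refit, and the overlap
of the selected features with the reference selection recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr


@dataclass
class SplsdaModel:
    n_components: int
    keep_per_component: int
    feature_names: np.ndarray
    feature_means: np.ndarray
    feature_sds: np.ndarray
    class_levels: np.ndarray
    loading_weights: np.ndarray  # features x components (sparse columns, unit norm)
    x_loadings: np.ndarray       # features x components
    rotation: np.ndarray         # features x components, T = Xstd @ rotation
    scores: np.ndarray           # training scores, samples x components


@dataclass
class RobustnessCurve:
    proportions: np.ndarray
    n_repeats: int
    overlap_fraction: np.ndarray  # repeats x proportions

    def mean_overlap(self) -> np.ndarray:
        return self.overlap_fraction.mean(axis=0)


def _dummy_code(labels) -> tuple[np.ndarray, np.ndarray]:
    levels, inv = np.unique(np.asarray(labels), return_inverse=True)
    Y = np.zeros((len(inv), len(levels)))
    Y[np.arange(len(inv)), inv] = 1.0
    return Y, levels


def _dominant_weight(M: np.ndarray, tol: float = 1e-12, max_iter: int = 1000) -> np.ndarray:
    """Leading left singular vector of M = X'Y by power iteration on M M'."""
    norms = np.linalg.norm(M, axis=0)
    w = M[:, int(np.argmax(norms))].copy()
    nw = np.linalg.norm(w)
    if nw == 0:
        return np.zeros(M.shape[0])
    w /= nw
    for _ in range(max_iter):
        w_new = M @ (M.T @ w)
        n = np.linalg.norm(w_new)
        if n == 0:
            break
        w_new /= n
        if np.linalg.norm(w_new - w) < tol:
            w = w_new
            break
        w = w_new
    # deterministic orientation: largest-magnitude entry positive
    j = int(np.argmax(np.abs(w)))
    return w * np.sign(w[j]) if w[j] != 0 else w


def _soft_threshold_keep(w: np.ndarray, keep: int) -> np.ndarray:
    if keep >= w.size:
        out = w.copy()
    else:
        a = np.abs(w)
        lam = np.partition(a, -keep - 1)[-keep - 1]
        out = np.sign(w) * np.maximum(a - lam, 0.0)
    n = np.linalg.norm(out)
    return out / n if n > 0 else out


def fit_splsda(X, labels, n_components: int = 6,
               keep_per_component: int = 2000) -> SplsdaModel:
    """Fit a sparse PLS-DA model.

    Parameters
    ----------
    X
        Samples x features matrix (DataFrame or ndarray).
    labels
        Class label per sample (>= 2 classes, each with >= 2 samples).
    keep_per_component
        Number of features with nonzero weight per component.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = X.columns.to_numpy()
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        feature_names = np.array([f"f{i}" for i in range(Xa.shape[1])])

    Y, levels = _dummy_code(labels)
    if len(levels) < 2:
        raise ValueError("need at least 2 classes")
    counts = Y.sum(axis=0)
    if (counts < 2).any():
        small = levels[counts < 2].tolist()
        raise ValueError(f"classes with fewer than 2 samples: {small}")

    sds = Xa.std(axis=0, ddof=1)
    const = sds == 0
    if const.any():
        warnings.warn(f"dropping {int(const.sum())} constant feature(s)")
        Xa = Xa[:, ~const]
        feature_names = feature_names[~const]
        sds = sds[~const]
    if keep_per_component > Xa.shape[1]:
        raise ValueError("keep_per_component exceeds number of usable features")

    means = Xa.mean(axis=0)
    Xd = (Xa - means) / sds
    Yd = Y - Y.mean(axis=0)

    p = Xd.shape[1]
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((Xd.shape[0], n_components))
    for a in range(n_components):
        w = _dominant_weight(Xd.T @ Yd)
        w = _soft_threshold_keep(w, keep_per_component)
        if not np.any(w):
            warnings.warn(f"component {a + 1} has zero weight; truncating model")
            W, P, T = W[:, :a], P[:, :a], T[:, :a]
            n_components = a
            break
        t = Xd @ w
        tt = float(t @ t)
        c = Xd.T @ t / tt
        d = Yd.T @ t / tt
        Xd = Xd - np.outer(t, c)
        Yd = Yd - np.outer(t, d)
        W[:, a], P[:, a], T[:, a] = w, c, t

    R = W @ np.linalg.inv(P.T @ W) if n_components else W
    return SplsdaModel(n_components=n_components,
                       keep_per_component=keep_per_component,
                       feature_names=feature_names, feature_means=means,
                       feature_sds=sds, class_levels=levels,
                       loading_weights=W, x_loadings=P, rotation=R, scores=T)


def selected_features(model: SplsdaModel) -> tuple[list[set], set]:
    """Nonzero-support feature sets per component and their union."""
    per_comp = [set(model.feature_names[model.loading_weights[:, a] != 0])
                for a in range(model.n_components)]
    union = set().union(*per_comp) if per_comp else set()
    return per_comp, union


def project(model: SplsdaModel, X_new, shared_features=None,
            min_shared: float = 0.5) -> np.ndarray:
    """Project new samples into the model's latent space.

    Features absent from ``shared_features`` are dropped from the rotation
    and each component rescaled by the inverse retained weight mass, so a
    platform missing part of the selection still yields comparable scores.
    Projection fails if fewer than ``min_shared`` of the selected features
    are available.
    """
    if isinstance(X_new, pd.DataFrame):
        cols = X_new.columns.to_numpy()
        Xa = X_new.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X_new, dtype=float)
        cols = model.feature_names
        if Xa.shape[1] != len(cols):
            raise ValueError("ndarray input must cover all model features")

    if shared_features is None:
        shared = set(cols) & set(model.feature_names)
    else:
        shared = set(shared_features) & set(cols) & set(model.feature_names)

    _, union = selected_features(model)
    if union and len(union & shared) < min_shared * len(union):
        raise ValueError(
            f"only {len(union & shared)} of {len(union)} selected features shared; "
            f"projection is not meaningful below {min_shared:.0%}")

    mpos = {f: i for i, f in enumerate(model.feature_names)}
    pairs = [(j, mpos[f]) for j, f in enumerate(cols) if f in shared]
    new_idx = np.array([j for j, _ in pairs])
    mod_idx = np.array([i for _, i in pairs])

    Xs = (Xa[:, new_idx] - model.feature_means[mod_idx]) / model.feature_sds[mod_idx]
    R = model.rotation[mod_idx]
    if len(mod_idx) < len(model.feature_names):
        full_mass = (model.loading_weights ** 2).sum(axis=0)
        kept_mass = (model.loading_weights[mod_idx] ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(kept_mass > 0, full_mass / kept_mass, 1.0)
        R = R * scale[None, :]
    return Xs @ R


def randomization_robustness(X, labels, n_components: int = 6,
                             keep_per_component: int = 2000,
                             proportions=(1.00, 0.75, 0.50, 0.25, 0.10, 0.05, 0.01),
                             n_repeats: int = 10, seed: int = 0) -> RobustnessCurve:
    """Feature-selection stability under partial label randomization.

    For each proportion p and repeat, labels of a random fraction p of the
    samples are permuted among themselves, the model refit, and the fraction
    of the reference selection recovered recorded.
    """
    labels = np.asarray(labels)
    ref = fit_splsda(X, labels, n_components, keep_per_component)
    _, ref_union = selected_features(ref)
    rng = np.random.default_rng(seed)
    props = np.asarray(proportions, dtype=float)
    overlap = np.zeros((n_repeats, len(props)))
    n = len(labels)
    for j, p in enumerate(props):
        m = int(round(p * n))
        for r in range(n_repeats):
            for _ in range(100):
                perturbed = labels.copy()
                if m >= 2:
                    idx = rng.choice(n, size=m, replace=False)
                    perturbed[idx] = rng.permutation(perturbed[idx])
                _, cnt = np.unique(perturbed, return_counts=True)
                if (cnt >= 2).all() and len(cnt) >= 2:
                    break
            else:
                raise RuntimeError("could not draw a permutation with viable classes")
            mod = fit_splsda(X, perturbed, n_components, keep_per_component)
            _, sel = selected_features(mod)
            overlap[r, j] = len(sel & ref_union) / max(len(ref_union), 1)
    return RobustnessCurve(proportions=props, n_repeats=n_repeats,
                           overlap_fraction=overlap)


def robustness_trend(curve: RobustnessCurve) -> tuple[float, float]:
    """Spearman trend (rho, p) of mean overlap against randomized proportion."""
    rho, p = spearmanr(curve.proportions, curve.mean_overlap())
    return float(rho), float(p)
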