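"""Per-cohort subtype discovery.

Dual clustering (Ward-D2 hierarchical and k-means) of LOAD samples, cluster
number selection by the elbow criterion and by hierarchical/k-means NMI
agreement, Hungarian-matched consensus labels, and batch-association checks.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.stats import spearmanr
from sklearn.cluster import KMeans
from sklearn.metrics import normalized_mutual_info_score

_NMI_AVG = {"max": "max", "sqrt": "geometric", "mean": "arithmetic", "min": "min"}


@dataclass
class ClusterAssignment:
    """Dual-method labels and their consensus for one cohort."""

    sample_ids: list[str]
    hierarchical_label: np.ndarray
    kmeans_label: np.ndarray
    consensus_label: list[str | None]
    k: int
    # hierarchical cluster id -> matched k-means cluster id
    matching: dict[int, int] = field(default_factory=dict)

    def consensus_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "hierarchical": self.hierarchical_label,
            "kmeans": self.kmeans_label,
            "consensus": self.consensus_label,
        })


@dataclass
class KSelection:
    k_range: list[int]
    wcss_curve: dict[int, float]
    nmi_per_k: dict[int, float]
    chosen_k: int
    low_confidence: bool = False


def hierarchical_cluster(X: np.ndarray, k: int) -> np.ndarray:
    """Ward-D2 agglomerative clustering on Euclidean distances, cut at k.

    scipy's ``ward`` linkage on raw (unsquared) Euclidean distances is the
    ward.D2 convention.  Labels are 1..k.
    """
    X = np.asarray(X, dtype=float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds n_samples={X.shape[0]}")
    if k < 1:
        raise ValueError("k must be >= 1")
    Z = linkage(X, method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


def kmeans_cluster(X: np.ndarray, k: int, seed: int = 0, n_init: int = 25) -> np.ndarray:
    """k-means with seeded multi-restart; labels are 1..k."""
    X = np.asarray(X, dtype=float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds n_samples={X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(X) + 1


def _wcss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        block = X[labels == lab]
        total += float(((block - block.mean(axis=0)) ** 2).sum())
    return total


def elbow_select(X: np.ndarray, method: str = "hierarchical",
                 k_range=range(2, 9), seed: int = 0,
                 flat_tol: float = 0.3) -> KSelection:
    """Elbow on the within-cluster sum-of-squares curve.

    The knee is the k maximizing the second forward difference of WCSS.
    A knee whose second difference is below ``flat_tol`` times the total
    WCSS drop over the curve is flagged low-confidence (smoothly decaying,
    structureless curve).  Non-monotone k-means curves are retried with
    more restarts before failing.
    """
    ks = sorted(k_range)
    if len(ks) < 3:
        raise ValueError("k_range must span at least 3 values")
    X = np.asarray(X, dtype=float)

    def curve(n_init):
        out = {}
        for k in ks:
            labels = (hierarchical_cluster(X, k) if method == "hierarchical"
                      else kmeans_cluster(X, k, seed=seed, n_init=n_init))
            out[k] = _wcss(X, labels)
        return out

    wcss = curve(25)
    vals = np.array([wcss[k] for k in ks])
    if method != "hierarchical" and np.any(np.diff(vals) > 1e-9 * vals[0]):
        wcss = curve(100)
        vals = np.array([wcss[k] for k in ks])
        if np.any(np.diff(vals) > 1e-6 * max(vals[0], 1.0)):
            raise RuntimeError("k-means WCSS curve not monotone after extra restarts")

    second = vals[:-2] - 2 * vals[1:-1] + vals[2:]
    best = int(np.argmax(second))
    chosen = ks[best + 1]
    drop = max(vals[0] - vals[-1], 1e-12)
    low = bool(second[best] < flat_tol * drop)
    return KSelection(k_range=ks, wcss_curve=wcss, nmi_per_k={},
                      chosen_k=chosen, low_confidence=low)


def nmi(labels_a, labels_b, variant: str = "max") -> float:
    """Normalized mutual information between two labelings."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("label vectors must be non-empty")
    if a.size != b.size:
        raise ValueError("label vectors must have equal length")
    return float(normalized_mutual_info_score(a, b, average_method=_NMI_AVG[variant]))


def select_k_by_nmi(X: np.ndarray, k_range=range(2, 9), seed: int = 0,
                    variant: str = "max", min_nmi: float = 0.3,
                    tie_tol: float = 1e-9) -> KSelection:
    """Choose k maximizing hierarchical-vs-k-means NMI agreement.

    Exact NMI ties are generic on well-separated data (merging or splitting
    clusters consistently keeps agreement at 1), so ties within ``tie_tol``
    are broken by the WCSS elbow (largest second forward difference) among
    the tied k values.  A maximal NMI below ``min_nmi`` flags the selection
    low-confidence (structureless data).
    """
    ks = sorted(k_range)
    X = np.asarray(X, dtype=float)
    nmis, wcss = {}, {}
    for k in ks:
        h = hierarchical_cluster(X, k)
        m = kmeans_cluster(X, k, seed=seed)
        nmis[k] = nmi(h, m, variant)
        wcss[k] = _wcss(X, h)
    if len(ks) == 1:
        chosen = ks[0]
    else:
        best = max(nmis.values())
        tied = [k for k in ks if nmis[k] >= best - tie_tol]
        if len(tied) == 1:
            chosen = tied[0]
        else:
            ext = dict(wcss)
            for k in {min(tied) - 1, max(tied) + 1}:
                if k not in ext and 1 <= k <= X.shape[0]:
                    ext[k] = _wcss(X, hierarchical_cluster(X, k))
            curv = {k: ext[k - 1] - 2 * ext[k] + ext[k + 1]
                    for k in tied if k - 1 in ext and k + 1 in ext}
            chosen = max(curv, key=curv.get) if curv else min(tied)
    return KSelection(k_range=ks, wcss_curve=wcss, nmi_per_k=nmis,
                      chosen_k=chosen, low_confidence=nmis[chosen] < min_nmi)


def _contingency(a: np.ndarray, b: np.ndarray, la, lb) -> np.ndarray:
    C = np.zeros((len(la), len(lb)), dtype=int)
    ia = {v: i for i, v in enumerate(la)}
    ib = {v: i for i, v in enumerate(lb)}
    for x, y in zip(a, b):
        C[ia[x], ib[y]] += 1
    return C


def consensus_labels(hier: np.ndarray, kmeans: np.ndarray,
                     sample_ids=None) -> ClusterAssignment:
    """Match k-means clusters to hierarchical clusters and keep agreements.

    Matching is optimal one-to-one assignment (Hungarian) on the contingency
    table; samples whose matched labels agree receive consensus letters
    A, B, C, ... in hierarchical-cluster order, others none.
    """
    hier = np.asarray(hier)
    kmeans = np.asarray(kmeans)
    la, lb = np.unique(hier), np.unique(kmeans)
    if len(la) != len(lb):
        raise ValueError(f"methods disagree on k: {len(la)} vs {len(lb)}")
    C = _contingency(hier, kmeans, la, lb)
    ri, ci = linear_sum_assignment(-C)
    matching = {int(la[i]): int(lb[j]) for i, j in zip(ri, ci)}
    letters = {int(h): string.ascii_uppercase[i] for i, h in enumerate(la)}
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(len(hier))]
    consensus = [letters[int(h)] if matching[int(h)] == int(m) else None
                 for h, m in zip(hier, kmeans)]
    return ClusterAssignment(sample_ids=list(sample_ids),
                             hierarchical_label=hier, kmeans_label=kmeans,
                             consensus_label=consensus, k=len(la),
                             matching=matching)


def batch_association(labels, batch_table: pd.DataFrame,
                      n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Association of cluster labels with technical/biological variables.

    Continuous columns: Spearman correlation of the variable with the labels
    as integer codes.  Discrete columns: NMI with a permutation p-value.
    Constant columns are reported as NA with a warning.
    """
    labels = np.asarray(labels)
    if batch_table.isna().any().any():
        raise ValueError("batch table contains missing values")
    codes = pd.factorize(labels)[0]
    rng = np.random.default_rng(seed)
    rows = []
    for col in batch_table.columns:
        v = batch_table[col]
        if v.nunique() <= 1:
            warnings.warn(f"variable {col!r} is constant; association undefined")
            rows.append({"variable": col, "kind": "constant",
                         "statistic": np.nan, "p": np.nan})
            continue
        if pd.api.types.is_numeric_dtype(v) and v.nunique() > 5:
            rho, p = spearmanr(codes, v.to_numpy())
            rows.append({"variable": col, "kind": "continuous",
                         "statistic": float(rho), "p": float(p)})
        else:
            vv = pd.factorize(v)[0]
            obs = nmi(codes, vv)
            null = np.empty(n_perm)
            for i in range(n_perm):
                null[i] = nmi(rng.permutation(codes), vv)
            p = (1 + np.sum(null >= obs - 1e-12)) / (1 + n_perm)
            rows.append({"variable": col, "kind": "discrete",
                         "statistic": obs, "p": float(p)})
    return pd.DataFrame(rows)
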