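"""Simplified co-methylation modules, eigenprobes and platform preservation.

Modules are detected from a signed soft-power adjacency on probe-probe
correlations with average-linkage tree cutting (a deliberately simplified
stand-in for topological-overlap network construction); each module is
summarized by its eigenprobe (first principal component over samples), and
cross-platform preservation is tested by recomputing eigenprobes on the
450K probe subset and requiring (a) the cluster-label ANOVA to stay
significant on both platforms and (b) per-cluster full-vs-subset eigenprobe
differences to be non-significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import f_oneway, ttest_rel
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class ModuleSet:
    module_of: pd.Series  # probe -> module id (0 = unassigned)
    soft_power: float
    cut_height: float
    min_size: int

    def members(self, module_id: int) -> pd.Index:
        return self.module_of.index[self.module_of == module_id]

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.module_of) - {0})


@dataclass
class Eigenprobe:
    module_id: int
    scores: pd.Series  # per sample
    explained_variance: float
    flipped: bool


def detect_modules(X: pd.DataFrame, soft_power: float = 6.0,
                   cut_height: float = 0.8, min_size: int = 10) -> ModuleSet:
    """Detect co-methylation modules from probes x samples data.

    Signed adjacency a_ij = ((1 + cor_ij)/2)^soft_power; average-linkage
    clustering of the dissimilarity 1 - a cut at ``cut_height``; clusters
    smaller than ``min_size`` are left unassigned (module 0).
    """
    if X.shape[0] < 3:
        raise ValueError("need at least 3 probes")
    vals = X.to_numpy(dtype=float)
    sds = vals.std(axis=1)
    const = sds == 0
    if const.any():
        warnings.warn(f"dropping {int(const.sum())} constant probe(s)")
    probes = X.index[~const]
    vals = vals[~const]

    corr = np.corrcoef(vals)
    adj = ((1.0 + corr) / 2.0) ** soft_power
    diss = 1.0 - adj
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2
    Z = linkage(squareform(diss, checks=False), method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")

    module_of = pd.Series(0, index=X.index, dtype=int)
    next_id = 1
    for lab in np.unique(raw):
        members = probes[raw == lab]
        if len(members) >= min_size:
            module_of.loc[members] = next_id
            next_id += 1
    return ModuleSet(module_of=module_of, soft_power=soft_power,
                     cut_height=cut_height, min_size=min_size)


def eigenprobe(X_module: pd.DataFrame, module_id: int = 1) -> Eigenprobe:
    """First principal component of the standardized module matrix.

    Samples are the observations; the sign is oriented so the eigenprobe
    correlates positively with the module's mean profile.
    """
    if X_module.shape[0] < 2:
        raise ValueError("module must contain at least 2 probes")
    vals = X_module.to_numpy(dtype=float)
    sds = vals.std(axis=1, keepdims=True)
    sds[sds == 0] = 1.0
    Z = (vals - vals.mean(axis=1, keepdims=True)) / sds
    # SVD of probes x samples standardized matrix: right singular vectors
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = Vt[0] * S[0] / np.sqrt(max(Z.shape[0], 1))
    explained = float(S[0] ** 2 / (S ** 2).sum())
    mean_profile = Z.mean(axis=0)
    flipped = False
    r = np.corrcoef(scores, mean_profile)[0, 1] if mean_profile.std() > 0 else 1.0
    if r < 0:
        scores = -scores
        flipped = True
    return Eigenprobe(module_id=module_id,
                      scores=pd.Series(scores, index=X_module.columns),
                      explained_variance=explained, flipped=flipped)


def module_cluster_association(eig: Eigenprobe, cluster_labels: pd.Series):
    """One-way ANOVA of eigenprobe scores across cluster labels + Tukey HSD."""
    labels = cluster_labels.loc[eig.scores.index]
    groups = [eig.scores[labels == g].to_numpy() for g in sorted(labels.unique())]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    F, p = f_oneway(*groups)
    tukey = pairwise_tukeyhsd(eig.scores.to_numpy(), labels.to_numpy())
    tukey_table = pd.DataFrame(tukey.summary().data[1:],
                               columns=tukey.summary().data[0])
    return float(F), float(p), tukey_table


def preservation_check(X_full: pd.DataFrame, subset_probes,
                       modules: ModuleSet, cluster_labels: pd.Series,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Cross-platform module preservation (EPIC -> 450K logic).

    Per module: recompute the eigenprobe using only probes present on the
    subset platform.  The module is preserved iff the cluster-label ANOVA is
    significant for both the full and subset eigenprobes and the per-cluster
    paired t-test between the two versions is non-significant for every
    cluster.  Modules losing all probes are reported non-evaluable.
    """
    subset = pd.Index(subset_probes)
    rows = []
    for mid in modules.module_ids:
        members = modules.members(mid)
        kept = members.intersection(subset)
        if len(kept) < 2:
            rows.append({"module": mid, "evaluable": False, "preserved": False,
                         "p_full": np.nan, "p_subset": np.nan,
                         "min_paired_p": np.nan, "n_probes_kept": len(kept)})
            continue
        eig_full = eigenprobe(X_full.loc[members], mid)
        eig_sub = eigenprobe(X_full.loc[kept], mid)
        labels = cluster_labels.loc[eig_full.scores.index]
        groups = sorted(labels.unique())
        _, p_full, _ = module_cluster_association(eig_full, cluster_labels)
        _, p_sub, _ = module_cluster_association(eig_sub, cluster_labels)
        paired_ps = []
        for g in groups:
            a = eig_full.scores[labels == g].to_numpy()
            b = eig_sub.scores[labels == g].to_numpy()
            if np.allclose(a, b):
                paired_ps.append(1.0)
            else:
                paired_ps.append(float(ttest_rel(a, b).pvalue))
        preserved = (p_full < alpha and p_sub < alpha
                     and all(p > alpha for p in paired_ps))
        rows.append({"module": mid, "evaluable": True, "preserved": bool(preserved),
                     "p_full": p_full, "p_subset": p_sub,
                     "min_paired_p": float(min(paired_ps)),
                     "n_probes_kept": len(kept)})
    return pd.DataFrame(rows)
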