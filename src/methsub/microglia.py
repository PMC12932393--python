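"""Microglial-state abundance, activation and morphology statistics.

Single-nucleus data enter as per-state pseudobulk profiles (summed counts
per sample) with per-sample cell counts.  The module computes proportional
state abundance with a <100-cells-per-group exclusion, a control-anchored
PCA projection with MAD outlier trimming and a permutation test on median
inter-group distances, marker-oriented PC1 activation scores standardized
against controls, the dual-significance pseudobulk DEA rule, and
morphology (PAM) group comparisons with Welch t and Cohen's d.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from ._utils import bh_adjust
from .containers import StatePseudobulk
from .expression import _tmm_factor, moderated_t_dea, tmm_logcpm


def _logcpm_control_anchored(counts: pd.DataFrame, control_cols,
                             prior_count: float = 0.5) -> pd.DataFrame:
    """TMM log-CPM against a control reference sample.

    The TMM reference is the control library whose upper quartile is closest
    to the control mean, and factors are left unnormalized, so changes to
    non-control samples can never alter the controls' normalized values
    (the projection must depend on control statistics only).
    """
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    cols = list(counts.columns)
    ctrl_idx = [cols.index(c) for c in control_cols]
    uq = np.array([np.percentile(X[:, j][X[:, j] > 0], 75) / lib[j]
                   for j in ctrl_idx])
    ref = ctrl_idx[int(np.argmin(np.abs(uq - uq.mean())))]
    f = np.array([_tmm_factor(X[:, j], X[:, ref]) for j in range(X.shape[1])])
    eff = lib * f
    prior = prior_count * eff / eff[ctrl_idx].mean()
    return np.log2((counts + prior).div(eff + 2.0 * prior, axis=1) * 1e6)


def pseudobulk_aggregate(cell_counts: pd.DataFrame, cell_states: pd.Series,
                         cell_samples: pd.Series,
                         groups: pd.Series | None = None,
                         marker_genes: dict[str, list[str]] | None = None
                         ) -> list[StatePseudobulk]:
    """Sum single-cell counts into per-state genes x samples pseudobulk.

    ``cell_counts`` is genes x cells; ``cell_states``/``cell_samples`` map
    each cell to its state and sample.  Empty state/sample combinations
    yield zero columns with cell count 0.
    """
    if not cell_states.index.equals(cell_counts.columns) and \
       set(cell_states.index) != set(cell_counts.columns):
        raise ValueError("cell state labels must cover all cells")
    samples = sorted(cell_samples.unique())
    out = []
    for state in sorted(cell_states.unique()):
        cells = cell_states.index[cell_states == state]
        mat = pd.DataFrame(0.0, index=cell_counts.index, columns=samples)
        ncells = pd.Series(0, index=samples, dtype=int)
        for sample in samples:
            members = [c for c in cells if cell_samples[c] == sample]
            if members:
                mat[sample] = cell_counts[members].sum(axis=1)
                ncells[sample] = len(members)
        grp = (groups.reindex(samples) if groups is not None
               else pd.Series("all", index=samples))
        out.append(StatePseudobulk(
            state=str(state), counts=mat, cell_counts=ncells, groups=grp,
            marker_genes=(marker_genes or {}).get(str(state), [])))
    return out


def state_proportions(cell_counts: pd.DataFrame, groups: pd.Series,
                      min_cells_per_group: int = 100):
    """Per-sample state proportions with group-level exclusion and testing.

    ``cell_counts`` is samples x states.  States with fewer than 100 cells
    in any group are excluded before testing; retained states are compared
    across groups by one-way ANOVA with Tukey HSD post hoc tests.
    """
    groups = groups.loc[cell_counts.index]
    if groups.value_counts().min() == 0:
        raise ValueError("every group needs at least one sample")
    totals = cell_counts.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("per-sample total cell counts must be positive")
    props = cell_counts.div(totals, axis=0)

    group_totals = cell_counts.groupby(groups).sum()
    retained = [s for s in cell_counts.columns
                if group_totals[s].min() >= min_cells_per_group]
    excluded = [s for s in cell_counts.columns if s not in retained]

    tests = []
    for state in retained:
        by_group = [props.loc[groups == g, state].to_numpy()
                    for g in sorted(groups.unique())]
        F, p = stats.f_oneway(*by_group)
        tk = pairwise_tukeyhsd(props[state].to_numpy(), groups.to_numpy())
        tk_table = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        tk_table["state"] = state
        tests.append({"state": state, "F": float(F), "p": float(p),
                      "tukey": tk_table})
    return props, pd.DataFrame([{k: t[k] for k in ("state", "F", "p")}
                                for t in tests]), \
        pd.concat([t["tukey"] for t in tests], ignore_index=True) if tests else pd.DataFrame(), \
        excluded


@dataclass
class PcaProjection:
    state: str
    scores: pd.DataFrame        # samples x [PC1, PC2], all groups
    groups: pd.Series
    loadings: np.ndarray
    gene_means: np.ndarray
    gene_sds: np.ndarray
    outliers_removed: list[str]
    explained_variance: np.ndarray
    genes: pd.Index = field(default=None)


def _pca_fit(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    # deterministic sign: largest-|loading| entry positive
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    var = S ** 2 / max(Z.shape[0] - 1, 1)
    return Vt, var


def control_pca_projection(pb: StatePseudobulk, control_group: str = "Control",
                           mad_factor: float = 3.5, var_target: float = 0.8,
                           min_controls: int = 5) -> PcaProjection:
    """Control-anchored PCA of one state's pseudobulk.

    TMM log-CPM expression is computed over all samples; PCA structure is
    defined on controls only.  Controls whose score-space distance from the
    median control exceeds median + 3.5 x MAD (distance measured over the
    components explaining >= 80% of control variance) are removed, the PCA
    refit on the cleaned controls, and every sample projected with the
    control gene means/sds and rotation.
    """
    nonzero = pb.counts.columns[pb.counts.sum(axis=0) > 0]
    groups_all = pb.groups.loc[nonzero]
    logcpm = _logcpm_control_anchored(
        pb.counts[nonzero], nonzero[groups_all == control_group])
    groups = pb.groups.loc[logcpm.columns]
    controls = logcpm.columns[groups == control_group]

    ctrl = logcpm[controls].to_numpy().T  # samples x genes
    sds = ctrl.std(axis=0, ddof=1)
    keep_genes = sds > 0
    if (~keep_genes).any():
        warnings.warn(f"{pb.state}: dropping {int((~keep_genes).sum())} "
                      "zero-variance gene(s) in controls")
    genes = logcpm.index[keep_genes]

    def standardize(cols):
        X = logcpm.loc[genes, cols].to_numpy().T
        return (X - mu[None, :]) / sd[None, :]

    mu = ctrl[:, keep_genes].mean(axis=0)
    sd = ctrl[:, keep_genes].std(axis=0, ddof=1)
    Z0 = standardize(controls)
    Vt, var = _pca_fit(Z0)
    cum = np.cumsum(var) / var.sum()
    ncomp = int(np.searchsorted(cum, var_target) + 1)
    T0 = Z0 @ Vt[:ncomp].T
    med = np.median(T0, axis=0)
    dist = np.linalg.norm(T0 - med, axis=1)
    mad = stats.median_abs_deviation(dist, scale="normal")
    thresh = np.median(dist) + mad_factor * (mad if mad > 0 else 1e-12)
    clean = dist <= thresh
    outliers = list(controls[~clean])

    kept_controls = controls[clean]
    if len(kept_controls) < min_controls:
        raise ValueError(f"{pb.state}: fewer than {min_controls} controls after cleaning")
    ctrl2 = logcpm.loc[genes, kept_controls].to_numpy().T
    mu = ctrl2.mean(axis=0)
    sd = ctrl2.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z1 = (ctrl2 - mu[None, :]) / sd[None, :]
    Vt, var = _pca_fit(Z1)

    all_samples = [s for s in logcpm.columns if s not in outliers]
    Z_all = standardize(all_samples)
    scores = pd.DataFrame(Z_all @ Vt[:2].T, index=all_samples,
                          columns=["PC1", "PC2"])
    return PcaProjection(state=pb.state, scores=scores,
                         groups=groups.loc[all_samples],
                         loadings=Vt[:2], gene_means=mu, gene_sds=sd,
                         outliers_removed=outliers,
                         explained_variance=var[:2] / var.sum(), genes=genes)


def median_intergroup_distance(scores: np.ndarray, labels: np.ndarray,
                               group_a, group_b, statistic: str = "pairwise") -> float:
    """Median cross-group distance in the 2-D score space.

    ``pairwise``: median over all cross-group sample pairs (default);
    ``centroid``: distance between group centroids.
    """
    A = scores[labels == group_a]
    B = scores[labels == group_b]
    if statistic == "centroid":
        return float(np.linalg.norm(A.mean(axis=0) - B.mean(axis=0)))
    d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
    return float(np.median(d))


def permutation_separation_test(projection: PcaProjection | None = None,
                                scores: np.ndarray | None = None,
                                labels=None, n_perm: int = 10_000, seed: int = 0,
                                statistic: str = "pairwise") -> pd.DataFrame:
    """Permutation test of group separation in PC1-PC2.

    For every group pair the observed median inter-group distance is
    compared against a null built by permuting group labels (group sizes
    preserved); empirical p = (1 + #{null >= obs})/(1 + n_perm) with the
    2.5/97.5 null percentiles as a confidence band, BH across pairs.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if projection is not None:
        scores = projection.scores.to_numpy()
        labels = projection.groups.to_numpy()
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    pairs = list(itertools.combinations(sorted(set(labels)), 2))
    for g in set(labels):
        if (labels == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")

    D = np.linalg.norm(scores[:, None, :] - scores[None, :, :], axis=2)
    rows = []
    for a, b in pairs:
        mask = (labels == a) | (labels == b)
        sub = D[np.ix_(mask, mask)]
        sub_labels = labels[mask]
        is_a = sub_labels == a
        obs = float(np.median(sub[np.ix_(is_a, ~is_a)]))
        n = len(sub_labels)
        na = int(is_a.sum())
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(n)
            pa = np.zeros(n, dtype=bool)
            pa[perm[:na]] = True
            null[i] = np.median(sub[np.ix_(pa, ~pa)])
        p = (1 + np.sum(null >= obs - 1e-12)) / (1 + n_perm)
        rows.append({"group_a": a, "group_b": b, "observed": obs,
                     "null_lo": float(np.percentile(null, 2.5)),
                     "null_hi": float(np.percentile(null, 97.5)),
                     "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


@dataclass
class ActivationScore:
    state: str
    scores: pd.Series   # oriented PC1 per sample
    z: pd.Series        # standardized vs controls
    groups: pd.Series
    t_s1_s2: float
    p_s1_s2: float


def activation_scores(pb: StatePseudobulk, control_group: str = "Control",
                      group_a: str = "LOAD-S1", group_b: str = "LOAD-S2") -> ActivationScore:
    """Marker-based activation score per sample for one state.

    PC1 of the marker-gene log-CPM matrix across all samples, sign-oriented
    to correlate positively with mean marker expression, standardized into
    Z-scores against controls, and compared S1-vs-S2 by Welch's t test.
    """
    if len(pb.marker_genes) < 2:
        raise ValueError("need at least 2 marker genes")
    logcpm = tmm_logcpm(pb.counts)
    M = logcpm.loc[pb.marker_genes].to_numpy().T  # samples x markers
    mu, sd = M.mean(axis=0), M.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (M - mu) / sd
    Vt, _ = _pca_fit(Z)
    pc1 = Z @ Vt[0]
    mean_marker = M.mean(axis=1)
    if np.corrcoef(pc1, mean_marker)[0, 1] < 0:
        pc1 = -pc1
    scores = pd.Series(pc1, index=logcpm.columns)
    groups = pb.groups.loc[scores.index]
    ctrl = scores[groups == control_group]
    if ctrl.std(ddof=1) == 0:
        raise ValueError("control activation scores are constant")
    z = (scores - ctrl.mean()) / ctrl.std(ddof=1)
    a = z[groups == group_a]
    b = z[groups == group_b]
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return ActivationScore(state=pb.state, scores=scores, z=z, groups=groups,
                           t_s1_s2=float(t), p_s1_s2=float(p))


def pseudobulk_dea(pb: StatePseudobulk, control_group: str = "Control",
                   group_a: str = "LOAD-S1", group_b: str = "LOAD-S2",
                   alpha: float = 0.05, min_per_side: int = 3) -> pd.DataFrame | None:
    """Dual-significance pseudobulk DEA for one state.

    Moderated-t contrasts A-vs-B, A-vs-control and B-vs-control on TMM
    log-CPM; a gene is flagged iff p < 0.05 in the subtype contrast AND
    p < 0.05 in at least one control contrast.  Returns None (with a
    warning) when any contrast lacks 3 samples per side.
    """
    groups = pb.groups
    sizes = groups.value_counts()
    for g in (control_group, group_a, group_b):
        if sizes.get(g, 0) < min_per_side:
            warnings.warn(f"{pb.state}: group {g!r} below {min_per_side} samples; skipped")
            return None
    logcpm = tmm_logcpm(pb.counts)

    def contrast(g1, g2):
        cols = groups.index[groups.isin([g1, g2])]
        return moderated_t_dea(logcpm[cols], groups.loc[cols]).table

    ab = contrast(group_a, group_b)
    ac = contrast(group_a, control_group)
    bc = contrast(group_b, control_group)
    out = pd.DataFrame({
        "p_s1_s2": ab["p"], "log2fc_s1_s2": ab["log2fc"],
        "p_s1_ctrl": ac["p"], "p_s2_ctrl": bc["p"],
    })
    out["significant"] = (out["p_s1_s2"] < alpha) & \
        ((out["p_s1_ctrl"] < alpha) | (out["p_s2_ctrl"] < alpha))
    return out


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with pooled standard deviation."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if sp == 0:
        return 0.0
    return float((a.mean() - b.mean()) / sp)


def morphology_compare(table: pd.DataFrame, measures=("pam",),
                       group_col: str = "group", region_col: str = "region"
                       ) -> pd.DataFrame:
    """Pairwise Welch t tests with Cohen's d per region and measure.

    BH correction is applied across all pairwise comparisons and regions
    within each measure.  Groups with fewer than 2 donors are skipped.
    """
    rows = []
    for measure in measures:
        for region, sub in table.groupby(region_col):
            groups = sorted(sub[group_col].unique())
            for a, b in itertools.combinations(groups, 2):
                va = sub.loc[sub[group_col] == a, measure].to_numpy()
                vb = sub.loc[sub[group_col] == b, measure].to_numpy()
                if len(va) < 2 or len(vb) < 2:
                    continue
                if np.allclose(va, va[0]) and np.allclose(vb, vb[0]) and va[0] == vb[0]:
                    t, p = 0.0, 1.0
                else:
                    t, p = stats.ttest_ind(va, vb, equal_var=False)
                rows.append({"measure": measure, "region": region,
                             "group_a": a, "group_b": b, "t": float(t),
                             "p": float(p), "cohens_d": cohens_d(va, vb)})
    out = pd.DataFrame(rows)
    for measure in measures:
        mask = out["measure"] == measure
        out.loc[mask, "q"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    return out
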