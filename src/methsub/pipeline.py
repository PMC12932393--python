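"""End-to-end subtype discovery and cross-cohort replication.

Chains the preprocessing, dual clustering, median-profile block matching
and convex-hull latent-space replication stages into a single call that
turns per-cohort beta matrices into confirmed subtype calls.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import (ClusterAssignment, KSelection, consensus_labels,
                      elbow_select, hierarchical_cluster, kmeans_cluster,
                      select_k_by_nmi)
from .containers import BetaMatrix
from .preprocess import filter_most_variable, residualize, spread_statistic
from .splsda import fit_splsda
from .replication import (HullReplication, SubtypeCall, calls_frame,
                          cluster_median_profiles, confirm_subtypes,
                          correlate_profiles, hull_replication, match_blocks)

DEFAULT_COVARIATES = ("age", "sex", "prop_neuron", "batch")


def choose_k(X: np.ndarray, k_range=range(2, 5), seed: int = 0,
             curvature_threshold: float = 0.01, min_nmi: float = 0.3) -> KSelection:
    """Cluster number from the WCSS elbow, validated by method agreement.

    The within-cluster sum-of-squares curve (Ward-D2 labels) is extended one
    k below the range; the chosen k is the largest one whose second forward
    difference exceeds ``curvature_threshold`` times the total sum of
    squares (the last significant knee before the curve flattens).  The
    hierarchical-vs-k-means NMI at the chosen k is recorded and flags the
    selection low-confidence below ``min_nmi``.
    """
    from .cluster import _wcss, hierarchical_cluster as _hc, kmeans_cluster as _km, nmi as _nmi

    ks = sorted(k_range)
    wcss = {}
    for k in range(max(ks[0] - 1, 1), ks[-1] + 2):
        wcss[k] = _wcss(X, _hc(X, k)) if k <= X.shape[0] else 0.0
    total = wcss[min(wcss)] if min(wcss) == 1 else max(wcss.values())
    curv = {k: (wcss[k - 1] - 2 * wcss[k] + wcss[k + 1]) / max(total, 1e-12)
            for k in ks if k - 1 in wcss and k + 1 in wcss}
    significant = [k for k, c in curv.items() if c >= curvature_threshold]
    chosen = max(significant) if significant else ks[0]
    agreement = _nmi(_hc(X, chosen), _km(X, chosen, seed=seed))
    return KSelection(k_range=ks, wcss_curve=wcss, nmi_per_k={chosen: agreement},
                      chosen_k=chosen, low_confidence=agreement < min_nmi)


@dataclass
class PipelineResult:
    calls: list[SubtypeCall]
    confirmed_blocks: list[dict]
    blocks: list[dict]
    assignments: dict[str, ClusterAssignment]
    k_selection: dict[str, KSelection]
    correlations: dict
    hull_results: dict[tuple[str, str, str], HullReplication]
    analysis_probes: pd.Index

    @property
    def n_confirmed(self) -> int:
        return len(self.confirmed_blocks)

    def calls_frame(self) -> pd.DataFrame:
        return calls_frame(self.calls)


def run_discovery_replication(
    beta_by_cohort: dict[str, BetaMatrix],
    annotations: pd.DataFrame,
    covariate_cols=DEFAULT_COVARIATES,
    spread_quantile: float = 0.5,
    k_range=range(2, 5),
    seed: int = 0,
    n_components: int = 2,
    keep_per_component: int = 200,
    alpha: float = 0.05,
    profile_on: str = "residuals",
) -> PipelineResult:
    """Discover and replicate methylation subtypes across cohorts.

    Per cohort: residualize betas against covariates, keep the most variable
    probes (on the probe panel shared by all cohorts), cluster the LOAD
    samples with Ward-D2 and k-means at the NMI-selected k, and form
    consensus labels.  Across cohorts: correlate cluster median profiles and
    group mutual best matches into blocks; fit sPLS-DA per discovery cohort
    and clustering method, project every other cohort, and test hull
    membership; confirm subtypes only where both lines of evidence agree in
    all rotations under both methods.
    """
    cohorts = sorted(beta_by_cohort)
    ann = annotations.set_index("sample_id")

    shared = None
    for c in cohorts:
        ids = beta_by_cohort[c].probe_ids
        shared = ids if shared is None else shared.intersection(ids)

    residuals, load_samples = {}, {}
    retained = None
    for c in cohorts:
        bm = beta_by_cohort[c]
        samples = list(bm.sample_ids)
        cov = ann.loc[samples, list(covariate_cols)]
        res = residualize(bm, cov)
        res.values = res.values.loc[res.values.index.intersection(shared)]
        residuals[c] = res
        keep = filter_most_variable(res, spread_quantile).values.index
        retained = keep if retained is None else retained.intersection(keep)
        load_samples[c] = [s for s in samples if ann.loc[s, "diagnosis"] == "LOAD"]
    analysis_probes = retained

    assignments, kselect = {}, {}
    for c in cohorts:
        X = residuals[c].values.loc[analysis_probes, load_samples[c]].T.to_numpy()
        ks = choose_k(X, k_range=k_range, seed=seed)
        h = hierarchical_cluster(X, ks.chosen_k)
        m = kmeans_cluster(X, ks.chosen_k, seed=seed)
        assignments[c] = consensus_labels(h, m, sample_ids=load_samples[c])
        kselect[c] = ks

    profiles = {}
    for c in cohorts:
        asg = assignments[c]
        labels = pd.Series(asg.consensus_label, index=asg.sample_ids).dropna()
        source = (residuals[c].values if profile_on == "residuals"
                  else beta_by_cohort[c].values)
        profiles[c] = cluster_median_profiles(source.loc[analysis_probes], labels)
    correlations = correlate_profiles(profiles)
    blocks = match_blocks(correlations)

    hull_results = {}
    for d in cohorts:
        Xd = residuals[d].values.loc[analysis_probes, load_samples[d]].T
        for method in ("hierarchical", "kmeans"):
            lab_d = getattr(assignments[d], f"{method}_label")
            model = fit_splsda(Xd, lab_d, n_components=n_components,
                               keep_per_component=min(keep_per_component,
                                                      len(analysis_probes)))
            for r in cohorts:
                if r == d:
                    continue
                Xr = residuals[r].values.loc[analysis_probes, load_samples[r]].T
                lab_r = getattr(assignments[r], f"{method}_label")
                hull_results[(d, r, method)] = hull_replication(
                    Xd, lab_d, Xr, lab_r, discovery=d, replication=r,
                    model=model)
    calls, confirmed = confirm_subtypes(blocks, hull_results, assignments,
                                        annotations, alpha=alpha)
    return PipelineResult(calls=calls, confirmed_blocks=confirmed, blocks=blocks,
                          assignments=assignments, k_selection=kselect,
                          correlations=correlations, hull_results=hull_results,
                          analysis_probes=analysis_probes)
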