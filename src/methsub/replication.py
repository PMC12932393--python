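"""Cross-cohort subtype replication.

Two independent lines of evidence are combined before a cluster is promoted
to a replicated subtype:

* probe level - per-cluster median methylation profiles are correlated
  across cohorts and clusters grouped into blocks of mutual best matches;
* sample level - sPLS-DA latent spaces (components 1-2) are fit per
  discovery cohort, convex hulls drawn around each discovery cluster,
  replication samples projected into the space, and the enrichment of each
  replication cluster inside each hull tested with a one-sided
  hypergeometric test (BH-corrected within each discovery->replication
  rotation).

A block becomes a subtype only when every within-block pair is significant
in both projection directions under both clustering methods; all other LOAD
samples are Unassigned.
"""

from __future__ import annotations

import itertools
import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import hypergeom, pearsonr

from ._utils import bh_adjust
from .cluster import ClusterAssignment
from .splsda import fit_splsda, project


@dataclass
class HullReplication:
    discovery: str
    replication: str
    table: pd.DataFrame  # rep_cluster, disc_cluster, inside, outside, p, q
    hulls: dict = field(default_factory=dict)  # disc cluster -> hull vertex array


@dataclass
class SubtypeCall:
    sample_id: str
    cohort: str
    call: str  # LOAD-S1 / LOAD-S2 / ... / Unassigned / Control
    block: str | None = None


def cluster_median_profiles(beta: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-cluster per-probe median over member samples.

    ``labels`` maps sample id -> cluster label (samples without a label are
    ignored); returns probes x clusters.
    """
    labels = labels.dropna()
    out = {}
    for lab in sorted(labels.unique()):
        members = labels.index[labels == lab]
        members = [m for m in members if m in beta.columns]
        if not members:
            warnings.warn(f"cluster {lab!r} has no samples in the matrix; skipped")
            continue
        out[lab] = beta[members].median(axis=1)
    return pd.DataFrame(out)


def correlate_profiles(profiles: dict[str, pd.DataFrame],
                       min_shared_probes: int = 100) -> dict[tuple[str, str], pd.DataFrame]:
    """Pearson correlation of cluster median profiles across cohort pairs.

    Returns, per unordered cohort pair, a DataFrame of r values (rows:
    first cohort's clusters, columns: second cohort's).
    """
    out = {}
    for c1, c2 in itertools.combinations(sorted(profiles), 2):
        p1, p2 = profiles[c1], profiles[c2]
        shared = p1.index.intersection(p2.index)
        if len(shared) < min_shared_probes:
            raise ValueError(
                f"cohort pair ({c1}, {c2}) shares only {len(shared)} probes "
                f"(floor {min_shared_probes})")
        R = pd.DataFrame(index=p1.columns, columns=p2.columns, dtype=float)
        for a in p1.columns:
            for b in p2.columns:
                R.loc[a, b] = pearsonr(p1.loc[shared, a], p2.loc[shared, b])[0]
        out[(c1, c2)] = R
    return out


def match_blocks(correlations: dict[tuple[str, str], pd.DataFrame]) -> list[dict[str, object]]:
    """Blocks of mutually best-matching clusters, one per cohort.

    A block is a tuple with one cluster per cohort such that within every
    cohort pair the two clusters are each other's best correlation match.
    """
    cohorts = sorted({c for pair in correlations for c in pair})
    if len(cohorts) < 3:
        raise ValueError("block matching requires at least 3 cohorts")

    def mutual_best(c1, c2):
        if (c1, c2) in correlations:
            R = correlations[(c1, c2)]
        else:
            R = correlations[(c2, c1)].T
        pairs = set()
        for a in R.index:
            b = R.loc[a].astype(float).idxmax()
            if R[b].astype(float).idxmax() == a:
                pairs.add((a, b))
        return pairs

    best = {(c1, c2): mutual_best(c1, c2)
            for c1, c2 in itertools.combinations(cohorts, 2)}
    c1, c2, *rest = cohorts
    blocks = []
    for a, b in sorted(best[(c1, c2)]):
        candidates = [{c1: a, c2: b}]
        for cr in rest:
            new = []
            for cand in candidates:
                for x, y in best[(c1, cr)]:
                    if x == cand[c1] and (cand[c2], y) in best[(c2, cr)]:
                        ok = all((cand[c], y) in best[(c, cr)] or c in (c1, c2)
                                 for c in cand)
                        if ok:
                            d = dict(cand)
                            d[cr] = y
                            new.append(d)
            candidates = new
        blocks.extend(candidates)
    return blocks


def _hull_inequalities(points: np.ndarray):
    """Hull facet inequalities A x <= b; handles degenerate point sets."""
    points = np.asarray(points, dtype=float)
    uniq = np.unique(points, axis=0)
    if len(uniq) >= 3:
        try:
            hull = ConvexHull(uniq)
            return hull.equations[:, :2], -hull.equations[:, 2], uniq[hull.vertices]
        except QhullError:
            warnings.warn("degenerate (collinear) cluster; zero-width hull used")
    # zero-width polygon: membership = on the segment between extremes
    return None, uniq, uniq


def _points_in_hull(pts: np.ndarray, ineq, tol: float = 1e-9) -> np.ndarray:
    A, b, _ = ineq
    pts = np.asarray(pts, dtype=float)
    if A is not None:
        return np.all(pts @ A.T <= b[None, :] + tol, axis=1)
    # degenerate: within tol of the segment spanned by the points in b
    seg = b
    if len(seg) == 1:
        return np.linalg.norm(pts - seg[0], axis=1) <= tol
    d = seg[-1] - seg[0]
    L2 = float(d @ d)
    t = np.clip(((pts - seg[0]) @ d) / L2, 0, 1)
    proj = seg[0] + t[:, None] * d
    return np.linalg.norm(pts - proj, axis=1) <= tol


def hull_replication(X_disc: pd.DataFrame, labels_disc,
                     X_rep: pd.DataFrame, labels_rep,
                     discovery: str = "discovery", replication: str = "replication",
                     n_components: int = 2, keep_per_component: int = 200,
                     model=None) -> HullReplication:
    """Convex-hull latent-space replication of one cohort pair.

    Fits sPLS-DA on the discovery cohort (samples x probes, labels), builds
    2-D hulls per discovery cluster on components 1-2, projects replication
    samples, and tests each (replication cluster, discovery hull) pair with
    a one-sided hypergeometric enrichment test; boundary points count as
    inside.  ``model`` may supply a pre-fitted discovery model.
    """
    labels_disc = np.asarray(labels_disc)
    labels_rep = np.asarray(labels_rep)
    if model is None:
        model = fit_splsda(X_disc, labels_disc, n_components=n_components,
                           keep_per_component=min(keep_per_component, X_disc.shape[1]))
    disc_scores = model.scores[:, :2]
    rep_scores = project(model, X_rep)[:, :2]

    hull_of = {lab: _hull_inequalities(disc_scores[labels_disc == lab])
               for lab in np.unique(labels_disc)}

    N = len(labels_rep)
    rows = []
    inside_flags = {lab: _points_in_hull(rep_scores, hull_of[lab]) for lab in hull_of}
    for rep_lab in np.unique(labels_rep):
        members = labels_rep == rep_lab
        n = int(members.sum())
        for disc_lab, flags in inside_flags.items():
            K = int(flags.sum())
            obs = int((flags & members).sum())
            p = float(hypergeom.sf(obs - 1, N, K, n))
            rows.append({"rep_cluster": rep_lab, "disc_cluster": disc_lab,
                         "inside": obs, "outside": n - obs, "p": p})
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    hulls = {lab: hull_of[lab][2] for lab in hull_of}
    return HullReplication(discovery=discovery, replication=replication,
                           table=table, hulls=hulls)


def _letter_maps(assignment: ClusterAssignment) -> dict[str, dict[str, int]]:
    """Consensus letter -> cluster id, for each clustering method."""
    hiers = sorted(np.unique(assignment.hierarchical_label))
    letters = {string.ascii_uppercase[i]: int(h) for i, h in enumerate(hiers)}
    return {"hierarchical": letters,
            "kmeans": {L: assignment.matching[h] for L, h in letters.items()}}


def confirm_subtypes(blocks: list[dict[str, object]],
                     hull_results: dict[tuple[str, str, str], HullReplication],
                     assignments: dict[str, ClusterAssignment],
                     annotations: pd.DataFrame,
                     alpha: float = 0.05) -> tuple[list[SubtypeCall], list[dict]]:
    """Combine block matching and hull tests into confirmed subtype calls.

    A correlation block is confirmed when, for every ordered cohort pair
    within it and under both clustering methods, the (replication cluster,
    discovery hull) hypergeometric test is BH-significant.  Samples in
    confirmed blocks get subtype names (LOAD-S1, LOAD-S2, ... in block
    order); other LOAD samples are Unassigned and controls Control.
    """
    cohorts = sorted(assignments)
    methods = ("hierarchical", "kmeans")
    for d, r in itertools.permutations(cohorts, 2):
        for m in methods:
            if (d, r, m) not in hull_results:
                raise ValueError(f"missing hull rotation ({d}, {r}, {m})")

    maps = {c: _letter_maps(assignments[c]) for c in cohorts}
    confirmed = []
    for block in blocks:
        ok = True
        for d, r in itertools.permutations(cohorts, 2):
            for m in methods:
                tab = hull_results[(d, r, m)].table
                dlab = maps[d][m][str(block[d])]
                rlab = maps[r][m][str(block[r])]
                row = tab[(tab["rep_cluster"] == rlab) & (tab["disc_cluster"] == dlab)]
                if row.empty or float(row["q"].iloc[0]) >= alpha:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            confirmed.append(block)

    block_name = {i: f"LOAD-S{i + 1}" for i in range(len(confirmed))}
    calls = []
    for _, row in annotations.iterrows():
        sid, cohort = row["sample_id"], row["cohort"]
        if row["diagnosis"] == "Control":
            calls.append(SubtypeCall(sid, cohort, "Control"))
            continue
        asg = assignments.get(cohort)
        call, blk = "Unassigned", None
        if asg is not None and sid in asg.sample_ids:
            letter = asg.consensus_label[asg.sample_ids.index(sid)]
            if letter is not None:
                for i, b in enumerate(confirmed):
                    if str(b.get(cohort)) == letter:
                        call, blk = block_name[i], f"block{i + 1}"
                        break
        calls.append(SubtypeCall(sid, cohort, call, blk))
    return calls, confirmed


def calls_frame(calls: list[SubtypeCall]) -> pd.DataFrame:
    return pd.DataFrame([{"sample_id": c.sample_id, "cohort": c.cohort,
                          "call": c.call, "block": c.block} for c in calls])
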