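"""Microglial-state abundance, activation scoring and morphology stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methsub.containers import StatePseudobulk
from methsub.microglia import (activation_scores, cohens_d,
                               control_pca_projection,
                               median_intergroup_distance, morphology_compare,
                               permutation_separation_test, pseudobulk_dea,
                               pseudobulk_aggregate, state_proportions)
from methsub.simulate import SimulationConfig, generate_microglia


@pytest.fixture(scope="module")
def microglia_study():
    return generate_microglia(SimulationConfig(seed=5))


def test_pseudobulk_aggregation_sums_and_batches():
    genes = ["g1", "g2"]
    cells = [f"c{i}" for i in range(6)]
    counts = pd.DataFrame([[1, 3, 5, 7, 9, 11], [2, 4, 6, 8, 10, 12]],
                          index=genes, columns=cells)
    states = pd.Series(["A", "A", "A", "B", "B", "B"], index=cells)
    samples = pd.Series(["s1", "s1", "s1", "s1", "s2", "s2"], index=cells)
    out = pseudobulk_aggregate(counts, states, samples)
    a = next(p for p in out if p.state == "A")
    assert a.counts.loc["g1", "s1"] == 9 and a.counts.loc["g2", "s1"] == 12
    assert a.cell_counts["s1"] == 3 and a.cell_counts["s2"] == 0
    assert (a.counts["s2"] == 0).all()
    # splitting cells into batches then aggregating preserves totals
    half1 = pseudobulk_aggregate(counts[cells[:3]], states[cells[:3]],
                                 samples[cells[:3]])
    half2 = pseudobulk_aggregate(counts[cells[3:]], states[cells[3:]],
                                 samples[cells[3:]])
    b_total = next(p for p in out if p.state == "B").counts
    b1 = next((p for p in half1 if p.state == "B"), None)
    b2 = next(p for p in half2 if p.state == "B")
    merged = (b1.counts.reindex(columns=b_total.columns, fill_value=0)
              if b1 is not None else 0) + \
        b2.counts.reindex(columns=b_total.columns, fill_value=0)
    pd.testing.assert_frame_equal(merged, b_total)


def test_state_proportions_normalize_and_exclude(microglia_study):
    pbs, cc = microglia_study
    props, anova, tukey, excluded = state_proportions(cc, pbs[0].groups)
    np.testing.assert_allclose(props.sum(axis=1), 1.0)
    assert "MG6" in excluded  # rare state below 100 cells in one group
    assert set(anova["state"]).isdisjoint(excluded)


def test_state_exclusion_boundary():
    cc = pd.DataFrame({"A": [1000] * 4, "B": [50, 49, 30, 40]},
                      index=["s1", "s2", "s3", "s4"])
    groups = pd.Series(["g1", "g1", "g2", "g2"], index=cc.index)
    props, anova, tukey, excluded = state_proportions(cc, groups)
    assert excluded == ["B"]  # 99 and 70 cells per group


def test_control_pca_outlier_removed_and_self_projection(microglia_study):
    pbs, _ = microglia_study
    pb = pbs[0]
    proj = control_pca_projection(pb)
    # displace one control compositionally (half the genes boosted 8x);
    # a uniform scaling would be absorbed by TMM normalization
    bad = pb.counts.copy().astype(float)
    ctrl_cols = pb.groups.index[pb.groups == "Control"]
    half = bad.index[: len(bad) // 2]
    bad.loc[half, ctrl_cols[0]] *= 8.0
    pb_bad = StatePseudobulk(state=pb.state, counts=bad,
                             cell_counts=pb.cell_counts, groups=pb.groups,
                             marker_genes=pb.marker_genes)
    proj_bad = control_pca_projection(pb_bad)
    assert ctrl_cols[0] in proj_bad.outliers_removed
    # control scores are centered by construction
    ctrl_scores = proj.scores.loc[[c for c in ctrl_cols
                                   if c not in proj.outliers_removed]]
    assert abs(ctrl_scores.mean().max()) < 1e-8


def test_projection_uses_only_control_statistics(microglia_study):
    pbs, _ = microglia_study
    pb = pbs[2]
    proj = control_pca_projection(pb)
    boosted = pb.counts.copy().astype(float)
    s1_cols = pb.groups.index[pb.groups == "LOAD-S1"]
    boosted[s1_cols] *= 5.0
    pb2 = StatePseudobulk(state=pb.state, counts=boosted,
                          cell_counts=pb.cell_counts, groups=pb.groups,
                          marker_genes=pb.marker_genes)
    proj2 = control_pca_projection(pb2)
    np.testing.assert_allclose(proj.loadings, proj2.loadings, atol=1e-10)


def test_permutation_test_floor_calibration_and_determinism(rng):
    scores = rng.normal(0, 1, (20, 2))
    labels = np.repeat(["a", "b"], 10)
    # strong separation hits the 1/(n_perm+1) floor
    far = scores.copy()
    far[10:] += 10.0
    out = permutation_separation_test(scores=far, labels=labels,
                                      n_perm=500, seed=3)
    assert out.loc[0, "p"] == pytest.approx(1 / 501)
    a = permutation_separation_test(scores=scores, labels=labels,
                                    n_perm=300, seed=7)
    b = permutation_separation_test(scores=scores, labels=labels,
                                    n_perm=300, seed=7)
    assert a.loc[0, "p"] == b.loc[0, "p"]
    with pytest.raises(ValueError, match="100"):
        permutation_separation_test(scores=scores, labels=labels, n_perm=50)


def test_median_distance_statistics(rng):
    A = np.zeros((5, 2))
    B = np.zeros((4, 2)) + [3.0, 4.0]
    scores = np.vstack([A, B])
    labels = np.array(["a"] * 5 + ["b"] * 4)
    assert median_intergroup_distance(scores, labels, "a", "b") == pytest.approx(5.0)
    assert median_intergroup_distance(scores, labels, "a", "b",
                                      statistic="centroid") == pytest.approx(5.0)


def test_activation_scores_orientation_and_standardization(microglia_study):
    pbs, _ = microglia_study
    shifted = next(p for p in pbs if p.state == "MG2")
    act = activation_scores(shifted)
    ctrl = act.z[act.groups == "Control"]
    assert ctrl.mean() == pytest.approx(0.0, abs=1e-12)
    assert ctrl.std(ddof=1) == pytest.approx(1.0)
    # planted +1 marker shift in LOAD-S1: S1 z-scores exceed S2's
    assert act.z[act.groups == "LOAD-S1"].mean() > act.z[act.groups == "LOAD-S2"].mean()
    assert act.p_s1_s2 < 0.01
    # orientation: the sample with highest marker expression scores highest
    from methsub.expression import tmm_logcpm
    lm = tmm_logcpm(shifted.counts).loc[shifted.marker_genes]
    assert act.scores.idxmax() == lm.mean(axis=0).idxmax()


def test_pseudobulk_dea_dual_rule(microglia_study):
    pbs, _ = microglia_study
    shifted = next(p for p in pbs if p.state == "MG2")
    out = pseudobulk_dea(shifted)
    markers = shifted.marker_genes
    assert out.loc[markers, "significant"].mean() > 0.9
    background = out.drop(index=markers)
    assert background["significant"].mean() < 0.1
    # rule application on constructed p-values
    row = pd.DataFrame({"p_s1_s2": [0.03, 0.03], "p_s1_ctrl": [0.04, 0.2],
                        "p_s2_ctrl": [0.5, 0.2]})
    flag = (row["p_s1_s2"] < 0.05) & ((row["p_s1_ctrl"] < 0.05)
                                      | (row["p_s2_ctrl"] < 0.05))
    assert flag.tolist() == [True, False]


def test_pseudobulk_dea_insufficient_samples_skipped(microglia_study):
    pbs, _ = microglia_study
    pb = pbs[0]
    few = pb.groups.copy()
    few[few == "LOAD-S2"] = "Control"
    few.iloc[-2:] = "LOAD-S2"
    pb2 = StatePseudobulk(state=pb.state, counts=pb.counts,
                          cell_counts=pb.cell_counts, groups=few,
                          marker_genes=pb.marker_genes)
    with pytest.warns(UserWarning, match="skipped"):
        assert pseudobulk_dea(pb2) is None


def test_welch_and_cohens_d_closed_forms():
    a, b = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
    assert cohens_d(a, b) == pytest.approx(-3.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0))
    table = pd.DataFrame({
        "donor": [f"d{i}" for i in range(6)],
        "group": ["x"] * 3 + ["y"] * 3,
        "region": ["r1"] * 6,
        "pam": [1, 2, 3, 4, 5, 6],
    })
    out = morphology_compare(table)
    assert out.loc[0, "cohens_d"] == pytest.approx(-3.0)
    assert out.loc[0, "t"] == pytest.approx(-3.674, abs=1e-3)
    same = table.copy()
    same["pam"] = [1, 2, 3, 1, 2, 3]
    out2 = morphology_compare(same)
    assert out2.loc[0, "cohens_d"] == pytest.approx(0.0)
    assert out2.loc[0, "p"] == pytest.approx(1.0)


def test_morphology_bh_within_measure(rng):
    rows = []
    for region in ("r1", "r2", "r3"):
        for g, mu in (("a", 0.3), ("b", 0.32)):
            for d in range(5):
                rows.append({"donor": f"{g}{d}{region}", "group": g,
                             "region": region,
                             "pam": mu + rng.normal(0, 0.05)})
    out = morphology_compare(pd.DataFrame(rows))
    assert (out["q"] >= out["p"] - 1e-12).all()
    assert len(out) == 3  # one pair per region
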