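"""Synthetic-study generator: determinism, null calibration, planted signals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methsub.simulate import (SimulationConfig, generate_methylation_cohorts,
                              generate_microglia, generate_morphology,
                              generate_study)
from .conftest import small_config


def test_seeded_determinism_methylation():
    a = generate_methylation_cohorts(small_config(seed=7))
    b = generate_methylation_cohorts(small_config(seed=7))
    for c in a.beta_by_cohort:
        pd.testing.assert_frame_equal(a.beta_by_cohort[c].values,
                                      b.beta_by_cohort[c].values)
    pd.testing.assert_frame_equal(a.annotations, b.annotations)


def test_betas_strictly_in_unit_interval(small_study):
    for bm in small_study.beta_by_cohort.values():
        v = bm.values.to_numpy()
        assert v.min() > 0 and v.max() < 1


def test_truth_labels_cover_every_load_sample(small_study):
    ann = small_study.annotations
    load = ann[ann.diagnosis == "LOAD"]
    labels = small_study.truth_labels
    assert set(load.sample_id) == set(labels.index)


def test_platform_mask_is_strict_subset(small_study):
    cohorts = sorted(small_study.beta_by_cohort)
    epic = set(small_study.beta_by_cohort[cohorts[0]].probe_ids)
    k450 = set(small_study.beta_by_cohort[cohorts[-1]].probe_ids)
    assert k450 < epic


def test_signature_sizes_exceeding_cpgs_rejected():
    with pytest.raises(ValueError, match="exceeds n_cpgs"):
        SimulationConfig(n_cpgs=100,
                         signature_sizes={"S1": 60, "S2": 60, "sharedLOAD": 0,
                                          "cohortSpecific": 0, "NFT-like": 0})


def test_null_effects_give_uniform_pvalues():
    """With all effects zero the group labels are exchangeable."""
    cfg = small_config(
        seed=5, n_cpgs=2000,
        effect_logit={k: 0.0 for k in ("S1", "S2", "sharedLOAD",
                                       "cohortSpecific", "NFT-like")},
        covariate_effects={},  # shared covariate terms correlate CpGs
        background_signature_sd=0.0, n_latent=0, severity_sd=0.0)
    study = generate_methylation_cohorts(cfg)
    ann = study.annotations.set_index("sample_id")
    bm = study.beta_by_cohort["cohort1"]
    s1 = [s for s in bm.sample_ids if ann.loc[s, "truth"] == "LOAD-S1"]
    s2 = [s for s in bm.sample_ids if ann.loc[s, "truth"] == "LOAD-S2"]
    t, p = stats.ttest_ind(bm.values[s1], bm.values[s2], axis=1)
    assert stats.kstest(p, "uniform").pvalue > 0.01


def test_planted_effect_recoverable_by_group_means():
    """effect 1.0 logit on the S1 signature moves mean beta by > 0.1."""
    cfg = small_config(seed=3, samples_per_group={"Control": 50, "LOAD-S1": 50,
                                                  "LOAD-S2": 50},
                       effect_logit={"S1": 1.0, "S2": 1.0, "sharedLOAD": 0.0,
                                     "cohortSpecific": 0.0, "NFT-like": 0.0},
                       signature_sizes={"S1": 200, "S2": 80, "sharedLOAD": 0,
                                        "cohortSpecific": 0, "NFT-like": 0})
    study = generate_methylation_cohorts(cfg)
    ann = study.annotations.set_index("sample_id")
    bm = study.beta_by_cohort["cohort2"]
    s1 = [s for s in bm.sample_ids if ann.loc[s, "truth"] == "LOAD-S1"]
    ctrl = [s for s in bm.sample_ids if ann.loc[s, "truth"] == "Control"]
    cpgs = [c for c in study.truth_registry["S1"] if c in bm.values.index]
    delta = (bm.values.loc[cpgs, s1].mean(axis=1)
             - bm.values.loc[cpgs, ctrl].mean(axis=1)).abs()
    assert delta.mean() > 0.1


def test_expression_determinism_and_linked_pairs(small_study):
    again = generate_study(small_config(), with_microglia=False,
                           with_morphology=False)
    for c in small_study.expression_by_cohort:
        pd.testing.assert_frame_equal(small_study.expression_by_cohort[c],
                                      again.expression_by_cohort[c])
    # planted monotone link: beta at the CpG tracks expression in LOAD-S2
    ann = small_study.annotations.set_index("sample_id")
    beta = small_study.beta_by_cohort["cohort1"].values
    expr = small_study.expression_by_cohort["cohort1"]
    s2 = [s for s in beta.columns if ann.loc[s, "truth"] == "LOAD-S2"]
    rhos = [stats.spearmanr(beta.loc[cpg, s2], expr.loc[gene, s2])[0]
            for cpg, gene in small_study.truth_registry["linked_pairs"]]
    assert np.median(rhos) > 0.5


def test_expression_null_fold_change_centers_on_zero():
    cfg = small_config(seed=9)
    cfg.expression["fold_change"] = 1.0
    study = generate_study(cfg, with_microglia=False, with_morphology=False)
    ann = study.annotations.set_index("sample_id")
    expr = study.expression_by_cohort["cohort2"]
    s1 = [s for s in expr.columns if ann.loc[s, "truth"] == "LOAD-S1"]
    ctrl = [s for s in expr.columns if ann.loc[s, "truth"] == "Control"]
    genes = study.truth_registry["deg_S1"]
    cpm = expr / expr.sum(axis=0) * 1e6  # remove library-size variation
    lr = np.log2((cpm.loc[genes, s1].mean(axis=1) + 1)
                 / (cpm.loc[genes, ctrl].mean(axis=1) + 1))
    assert abs(lr.mean()) < 0.1


def test_linked_pairs_exceeding_planted_cpgs_rejected(small_study):
    cfg = small_config()
    cfg.expression["n_linked_pairs"] = 10 ** 6
    from methsub.simulate import generate_expression
    with pytest.raises(ValueError, match="n_linked_pairs"):
        generate_expression(small_study, cfg)


def test_microglia_shift_and_rare_state():
    cfg = SimulationConfig(seed=4)
    pbs, cc = generate_microglia(cfg)
    again, cc2 = generate_microglia(cfg)
    pd.testing.assert_frame_equal(cc, cc2)
    shifted = next(p for p in pbs if p.state == "MG2")
    groups = shifted.groups
    lm = np.log2(shifted.counts.loc[shifted.marker_genes] + 1)
    s1 = lm.loc[:, groups == "LOAD-S1"].to_numpy().mean()
    ctrl = lm.loc[:, groups == "Control"].to_numpy().mean()
    assert s1 > ctrl
    group_totals = cc.groupby(groups).sum()
    assert (group_totals < 100).any().any()  # exercises the exclusion rule


def test_microglia_overlapping_markers_rejected():
    cfg = SimulationConfig(seed=0)
    cfg.microglia["n_states"] = 10
    cfg.microglia["markers_per_state"] = 100
    cfg.microglia["n_genes"] = 300
    with pytest.raises(ValueError, match="overlap"):
        generate_microglia(cfg)


def test_morphology_bounds_variance_and_determinism():
    cfg = SimulationConfig(seed=6)
    cfg.morphology["n_donors"] = 100
    m1 = generate_morphology(cfg)
    m2 = generate_morphology(cfg)
    pd.testing.assert_frame_equal(m1, m2)
    assert m1.pam.between(0, 1).all()
    v = m1.groupby("group").pam.var()
    assert v["LOAD-S1"] / v["LOAD-S2"] > 2  # configured 4x variance
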