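"""Bulk RNA-seq normalization, differential expression and CpG-mRNA links.

Implements TMM scaling-factor normalization with log-CPM transformation, a
moderated-t differential expression test with empirical-Bayes variance
shrinkage, the three-cohort consensus filter for differentially expressed
genes, and TSS-window Spearman correlation of methylation with expression,
replicated across cohorts at FDR < 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from ._utils import bh_adjust


def filter_low_expression(counts: pd.DataFrame, min_count: int = 10,
                          max_low_fraction: float = 0.8) -> pd.DataFrame:
    """Drop genes with counts below ``min_count`` in over 80% of samples."""
    if counts.shape[1] < 1:
        raise ValueError("need at least one sample")
    low_frac = (counts < min_count).sum(axis=1) / counts.shape[1]
    return counts.loc[low_frac <= max_low_fraction]


def _tmm_factor(obs: np.ndarray, ref: np.ndarray,
                logratio_trim: float = 0.3, sum_trim: float = 0.05) -> float:
    """TMM factor of one sample against the reference library."""
    n_o, n_r = obs.sum(), ref.sum()
    ok = (obs > 0) & (ref > 0)
    o, r = obs[ok] / n_o, ref[ok] / n_r
    M = np.log2(o / r)
    A = 0.5 * np.log2(o * r)
    # asymptotic variance of M (delta method) -> precision weights
    v = (n_o - obs[ok]) / (n_o * obs[ok]) + (n_r - ref[ok]) / (n_r * ref[ok])
    if len(M) == 0:
        return 1.0
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = len(M)
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - (np.floor(n * logratio_trim) + 1)
    lo_a, hi_a = np.floor(n * sum_trim) + 1, n + 1 - (np.floor(n * sum_trim) + 1)
    rank_m = stats.rankdata(M)
    rank_a = stats.rankdata(A)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per sample.

    The reference is the sample whose upper-quartile (of the library-scaled
    counts) is closest to the mean upper-quartile; factors are normalized to
    geometric mean 1.
    """
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"zero library size in samples: {bad}")
    uq = np.array([np.percentile(X[:, j][X[:, j] > 0], 75) / lib[j]
                   if (X[:, j] > 0).any() else 0.0 for j in range(X.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    f = np.array([_tmm_factor(X[:, j], X[:, ref]) for j in range(X.shape[1])])
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns)


def tmm_logcpm(counts: pd.DataFrame, prior_count: float = 0.5) -> pd.DataFrame:
    """TMM-normalized log2 counts-per-million.

    The prior count is scaled by each sample's effective library size so a
    pure sequencing-depth change leaves logCPM exactly invariant.
    """
    f = tmm_factors(counts)
    lib = counts.sum(axis=0) * f
    prior = prior_count * lib / lib.mean()
    return np.log2((counts + prior).div(lib + 2.0 * prior, axis=1) * 1e6)


def _trigamma_inverse(y: float) -> float:
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def _squeeze_var(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Empirical-Bayes prior df d0 and scale s0^2 from log-variance moments."""
    z = np.log(np.maximum(s2, 1e-300))
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(e, ddof=1) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(np.mean(z)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0 = float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0


@dataclass
class DegResult:
    table: pd.DataFrame  # log2fc, t, p, fdr
    cohort: str
    d0: float
    s0_sq: float


def moderated_t_dea(expr: pd.DataFrame, groups, covariates: pd.DataFrame | None = None,
                    cohort: str = "cohort", prior_df: float | None = None) -> DegResult:
    """Moderated-t differential expression on log-scale expression.

    ``groups`` must have exactly two levels; the coefficient of the second
    (sorted) level is the log2 fold change when ``expr`` is log2 scale.
    Residual variances are shrunk toward a common prior estimated by
    method-of-moments on log variances; the moderated t has df + d0 degrees
    of freedom.
    """
    g = pd.Series(np.asarray(groups), index=expr.columns)
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError("moderated_t_dea expects exactly two groups")
    y = (g == levels[1]).astype(float).to_numpy()
    parts = [np.ones_like(y), y]
    names = ["intercept", "group"]
    if covariates is not None and covariates.shape[1]:
        Xc = pd.get_dummies(covariates.loc[expr.columns], drop_first=True, dtype=float)
        parts += [Xc[c].to_numpy() for c in Xc.columns]
        names += list(Xc.columns)
    D = np.column_stack(parts)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("rank-deficient design")
    n, p = D.shape
    df = n - p
    DtD_inv = np.linalg.inv(D.T @ D)
    coef = (DtD_inv @ D.T @ expr.to_numpy(dtype=float).T)
    resid = expr.to_numpy(dtype=float).T - D @ coef
    s2 = (resid ** 2).sum(axis=0) / df

    if prior_df is None:
        d0, s0 = _squeeze_var(s2, df)
    else:
        d0 = prior_df
        s0 = float(np.exp(np.mean(np.log(np.maximum(s2, 1e-300))))) if d0 else 0.0
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = 1e6
    else:
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        df_total = df + d0
    unscaled = np.sqrt(DtD_inv[1, 1])
    tstat = coef[1] / (np.sqrt(s2_post) * unscaled)
    pvals = 2 * stats.t.sf(np.abs(tstat), df_total)
    table = pd.DataFrame({"log2fc": coef[1], "t": tstat, "p": pvals,
                          "fdr": bh_adjust(pvals)}, index=expr.index)
    return DegResult(table=table, cohort=cohort, d0=float(d0), s0_sq=s0)


def cross_cohort_deg_filter(results: dict[str, DegResult] | dict[str, pd.DataFrame],
                            fc_threshold: float = 1.5, p_threshold: float = 0.05,
                            fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Consensus DEG rule across three cohorts.

    A gene is retained iff the log2FC sign agrees in all cohorts, the linear
    fold change exceeds ``fc_threshold`` in at least one, p < 0.05 in all,
    and FDR < 0.05 in at least one.  Genes missing from any cohort are
    excluded.
    """
    tables = {c: (r.table if isinstance(r, DegResult) else r)
              for c, r in results.items()}
    if len(tables) < 3:
        raise ValueError("consensus filter expects three cohorts")
    genes = None
    for t in tables.values():
        genes = t.index if genes is None else genes.intersection(t.index)
    lfc = np.column_stack([tables[c].loc[genes, "log2fc"] for c in tables])
    pv = np.column_stack([tables[c].loc[genes, "p"] for c in tables])
    fdr = np.column_stack([tables[c].loc[genes, "fdr"] for c in tables])
    sign_ok = (np.sign(lfc) == np.sign(lfc[:, [0]])).all(axis=1) & (lfc[:, 0] != 0)
    fc_ok = (np.abs(lfc) > np.log2(fc_threshold)).any(axis=1)
    p_ok = (pv < p_threshold).all(axis=1)
    fdr_ok = (fdr < fdr_threshold).any(axis=1)
    keep = sign_ok & fc_ok & p_ok & fdr_ok
    out = pd.DataFrame({"gene": genes[keep]}).set_index("gene")
    for i, c in enumerate(tables):
        out[f"log2fc_{c}"] = lfc[keep, i]
    return out


def cpg_gene_pairs(cpg_coords: pd.DataFrame, gene_tss: pd.DataFrame,
                   window: int = 10_000) -> pd.DataFrame:
    """Candidate CpG-gene pairs with the CpG within TSS +/- window (inclusive).

    ``cpg_coords`` indexed by CpG id with chrom/pos; ``gene_tss`` indexed by
    gene id with chrom/tss.
    """
    rows = []
    for chrom, genes in gene_tss.groupby("chrom"):
        cpgs = cpg_coords[cpg_coords["chrom"] == chrom]
        if cpgs.empty:
            continue
        pos = cpgs["pos"].to_numpy()
        order = np.argsort(pos)
        pos_sorted = pos[order]
        ids_sorted = cpgs.index.to_numpy()[order]
        for gene, tss in genes["tss"].items():
            lo = np.searchsorted(pos_sorted, tss - window, side="left")
            hi = np.searchsorted(pos_sorted, tss + window, side="right")
            for i in range(lo, hi):
                rows.append({"cpg": ids_sorted[i], "gene": gene,
                             "distance": int(pos_sorted[i] - tss)})
    return pd.DataFrame(rows, columns=["cpg", "gene", "distance"])


def correlate_cpg_expression(beta_by_cohort: dict[str, pd.DataFrame],
                             expr_by_cohort: dict[str, pd.DataFrame],
                             pairs: pd.DataFrame,
                             subtype_of: pd.Series,
                             fdr_threshold: float = 0.1,
                             min_samples: int = 5) -> pd.DataFrame:
    """Spearman CpG-expression correlation per subtype per cohort.

    p-values are BH-corrected within each (cohort, subtype) family; a pair
    is flagged replicated for a subtype when FDR < 0.1 in at least two
    cohorts.  Strata with fewer than ``min_samples`` samples are skipped.
    """
    subtypes = sorted(s for s in subtype_of.unique()
                      if s not in ("Control", "Unassigned"))
    records = []
    for cohort in sorted(beta_by_cohort):
        beta, expr = beta_by_cohort[cohort], expr_by_cohort[cohort]
        samples = beta.columns.intersection(expr.columns)
        for subtype in subtypes:
            members = [s for s in samples if subtype_of.get(s) == subtype]
            if len(members) < min_samples:
                warnings.warn(f"{cohort}/{subtype}: only {len(members)} samples; skipped")
                continue
            sub_p = []
            for cpg, gene in pairs[["cpg", "gene"]].itertuples(index=False):
                if cpg not in beta.index or gene not in expr.index:
                    sub_p.append((cpg, gene, np.nan, np.nan))
                    continue
                rho, p = stats.spearmanr(beta.loc[cpg, members],
                                         expr.loc[gene, members])
                sub_p.append((cpg, gene, rho, p))
            frame = pd.DataFrame(sub_p, columns=["cpg", "gene", "rho", "p"])
            valid = frame["p"].notna()
            frame.loc[valid, "fdr"] = bh_adjust(frame.loc[valid, "p"].to_numpy())
            frame["cohort"] = cohort
            frame["subtype"] = subtype
            records.append(frame)
    long = pd.concat(records, ignore_index=True)
    sig = (long[long["fdr"] < fdr_threshold]
           .groupby(["cpg", "gene", "subtype"]).size().rename("n_sig"))
    long = long.merge(sig.reset_index(), on=["cpg", "gene", "subtype"], how="left")
    long["n_sig"] = long["n_sig"].fillna(0).astype(int)
    long["replicated"] = long["n_sig"] >= 2
    return long
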