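"""Subtype EWAS with surrogate variables, bias/inflation correction and
inverse-variance meta-analysis.

Per cohort, each CpG is regressed on the subtype contrast plus covariates
and data-driven surrogate variables; per-cohort test statistics are
de-biased and de-inflated with an empirical-Bayes three-component normal
mixture (the central component's mean and sd estimate bias and inflation);
cohorts are pooled by fixed-effect inverse-variance weighting (optional
DerSimonian-Laird random effects) and differentially methylated positions
called at a Bonferroni-adjusted p below 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EwasResult:
    table: pd.DataFrame  # index cpg: estimate, se, z, p
    cohort: str
    covariates: list[str]
    n_surrogates: int


@dataclass
class BaconFit:
    bias: float
    inflation: float
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    z_corrected: np.ndarray
    estimates_corrected: np.ndarray
    ses_corrected: np.ndarray


def _design_matrix(outcome, covariates: pd.DataFrame | None,
                   surrogates: np.ndarray | None) -> tuple[np.ndarray, list[str]]:
    y = np.asarray(outcome, dtype=float)
    parts = [np.ones_like(y), y]
    names = ["intercept", "outcome"]
    if covariates is not None and covariates.shape[1]:
        X = pd.get_dummies(covariates, drop_first=True, dtype=float)
        for c in X.columns:
            parts.append(X[c].to_numpy(dtype=float))
            names.append(str(c))
    if surrogates is not None and np.size(surrogates):
        sv = np.atleast_2d(np.asarray(surrogates, dtype=float))
        if sv.shape[0] == len(y) and sv.shape[1] != len(y):
            sv = sv.T
        for i in range(sv.shape[0]):
            parts.append(sv[i])
            names.append(f"sv{i + 1}")
    D = np.column_stack(parts)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        _, R = np.linalg.qr(D)
        dep = [names[j] for j in range(D.shape[1]) if abs(R[j, j]) < 1e-10]
        raise ValueError(f"design matrix rank deficient; collinear columns: {dep}")
    return D, names


def estimate_svs(data: pd.DataFrame, outcome, covariates: pd.DataFrame | None = None,
                 n_perm: int = 20, seed: int = 0, quantile: float = 0.95,
                 max_svs: int = 10, excess: float = 1.05) -> np.ndarray:
    """Surrogate variables by permutation parallel analysis.

    The probes x samples matrix is residualized on outcome + covariates;
    singular values of the residual matrix are compared against the given
    quantile of singular values from row-wise permuted (and re-residualized,
    variance-matched) data, and right singular vectors of the components
    exceeding it are returned (samples x k, possibly k = 0).  Permutation
    nulls are slightly deflated by the within-row sampling-without-
    replacement constraint, so a component must exceed the null threshold
    by the ``excess`` factor to count.
    """
    D, _ = _design_matrix(outcome, covariates, None)
    if data.shape[1] < D.shape[1] + 3:
        raise ValueError("too few samples for surrogate estimation")
    Y = data.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(D, Y.T, rcond=None)
    R = Y - (D @ coef).T

    sv = np.linalg.svd(R, compute_uv=False)
    rng = np.random.default_rng(seed)
    null = np.zeros((n_perm, len(sv)))
    H = D @ np.linalg.inv(D.T @ D) @ D.T
    Rp = R.copy()
    normR = np.linalg.norm(R)
    for b in range(n_perm):
        for i in range(Rp.shape[0]):
            rng.shuffle(Rp[i])
        # re-residualize so the null matrix lives in the same subspace,
        # rescaled to the observed total variance (projection sheds ~p/n)
        Rn = Rp - Rp @ H
        scale = normR / max(np.linalg.norm(Rn), 1e-300)
        null[b] = np.linalg.svd(Rn, compute_uv=False) * scale
    thresh = np.quantile(null, quantile, axis=0) * excess
    k = 0
    while k < min(max_svs, len(sv)) and sv[k] > thresh[k]:
        k += 1
    if k == 0:
        return np.zeros((data.shape[1], 0))
    _, _, Vt = np.linalg.svd(R, full_matrices=False)
    return Vt[:k].T


def run_ewas(beta: pd.DataFrame, outcome, covariates: pd.DataFrame | None = None,
             surrogates: np.ndarray | None = None,
             cohort: str = "cohort") -> EwasResult:
    """Per-CpG OLS of methylation on the outcome contrast plus adjustments.

    Returns the outcome coefficient, its standard error, z and two-sided p
    (normal reference on the large-sample Wald statistic) per CpG.
    """
    D, names = _design_matrix(outcome, covariates, surrogates)
    Y = beta.to_numpy(dtype=float)
    n, p = D.shape
    DtD_inv = np.linalg.inv(D.T @ D)
    H = DtD_inv @ D.T
    coef = H @ Y.T  # p x probes
    resid = Y.T - D @ coef
    df = n - p
    sigma2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(sigma2 * DtD_inv[1, 1])
    est = coef[1]
    z = est / se
    pvals = 2 * stats.t.sf(np.abs(z), df)
    table = pd.DataFrame({"estimate": est, "se": se, "z": z, "p": pvals},
                         index=beta.index)
    nsv = 0 if surrogates is None else np.atleast_2d(surrogates).shape[1]
    return EwasResult(table=table, cohort=cohort, covariates=names[2:],
                      n_surrogates=nsv)


def bacon_correct(estimates, ses, seed: int = 0, max_iter: int = 1000,
                  tol: float = 1e-8, side_separation: float = 2.0) -> BaconFit:
    """Empirical-Bayes bias/inflation correction of z-scores.

    A three-component normal mixture is fit to z = estimate/se by
    expectation-maximization; the central (largest-weight) component's mean
    and sd are the bias and inflation.  Corrected quantities satisfy
    z_corrected = (z - bias)/inflation, with estimate_c = estimate - bias*se
    and se_c = se * inflation.
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if not (np.all(np.isfinite(est)) and np.all(np.isfinite(se)) and np.all(se > 0)):
        raise ValueError("estimates/ses must be finite with positive ses")
    z = est / se
    n = z.size
    if n < 1000:
        warnings.warn("fewer than 1000 tests; bias/inflation estimates unstable")

    med, mad = np.median(z), stats.median_abs_deviation(z, scale="normal")
    mad = mad if mad > 0 else 1.0
    w = np.array([0.9, 0.05, 0.05])
    mu = np.array([med, med - 3 * mad, med + 3 * mad])
    sd = np.array([mad, 2 * mad, 2 * mad])

    loglik_old = -np.inf
    for it in range(max_iter):
        dens = np.stack([wk * stats.norm.pdf(z, m, s)
                         for wk, m, s in zip(w, mu, sd)])
        total = dens.sum(axis=0)
        total[total == 0] = np.finfo(float).tiny
        resp = dens / total
        loglik = float(np.log(total).sum())
        nk = resp.sum(axis=1)
        w = nk / n
        mu = (resp @ z) / nk
        sd = np.sqrt(np.maximum((resp * (z[None, :] - mu[:, None]) ** 2).sum(axis=1) / nk,
                                1e-6))
        # central component = largest weight; side means pushed outside it
        order = np.argsort(-w)
        w, mu, sd = w[order], mu[order], sd[order]
        lo = 1 if mu[1] <= mu[2] else 2
        hi = 3 - lo  # index of the right-side component among {1,2}
        mu[lo] = min(mu[lo], mu[0] - side_separation * sd[0])
        mu[hi] = max(mu[hi], mu[0] + side_separation * sd[0])
        if abs(loglik - loglik_old) < tol * (1 + abs(loglik)):
            break
        loglik_old = loglik
    else:
        raise RuntimeError(
            f"bacon EM did not converge after {max_iter} iterations "
            f"(last loglik change {loglik - loglik_old:.3e})")

    bias, inflation = float(mu[0]), float(sd[0])
    z_c = (z - bias) / inflation
    return BaconFit(bias=bias, inflation=inflation, weights=w, means=mu, sds=sd,
                    z_corrected=z_c, estimates_corrected=est - bias * se,
                    ses_corrected=se * inflation)


def genomic_inflation(z: np.ndarray) -> float:
    """Genomic inflation factor: median chi-square over its null median."""
    return float(np.median(np.asarray(z) ** 2) / stats.chi2.ppf(0.5, 1))


def meta_analyze(results: list[EwasResult] | list[pd.DataFrame],
                 method: str = "fixed", alpha: float = 0.05) -> pd.DataFrame:
    """Inverse-variance meta-analysis across cohorts with Bonferroni DMPs.

    Fixed-effect pooling by default; ``method='random'`` adds a
    DerSimonian-Laird tau-squared.  CpGs present in a single cohort are
    reported unpooled with ``single_cohort=True``; the Bonferroni
    denominator is the number of CpGs entering the meta-analysis.
    """
    tables = [r.table if isinstance(r, EwasResult) else r for r in results]
    if len(tables) < 2:
        raise ValueError("need at least 2 cohorts")
    all_cpgs = tables[0].index
    for t in tables[1:]:
        all_cpgs = all_cpgs.union(t.index)

    E = np.column_stack([t.reindex(all_cpgs)["estimate"].to_numpy() for t in tables])
    S = np.column_stack([t.reindex(all_cpgs)["se"].to_numpy() for t in tables])
    present = np.isfinite(E) & np.isfinite(S)
    k = present.sum(axis=1)
    if (k == 0).any():
        raise ValueError("CpG with no cohort data")

    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(present, 1.0 / S ** 2, 0.0)
    sw = w.sum(axis=1)
    fixed = np.einsum("ij,ij->i", w, np.nan_to_num(E)) / sw
    Q = np.einsum("ij,ij->i", w, np.nan_to_num((E - fixed[:, None]) ** 2,
                                               nan=0.0) * present)
    tau2 = np.zeros_like(fixed)
    if method == "random":
        c = sw - (w ** 2).sum(axis=1) / sw
        tau2 = np.where(c > 0, np.maximum(0.0, (Q - (k - 1)) / np.where(c > 0, c, 1.0)),
                        0.0)
        w = np.where(present, 1.0 / (S ** 2 + tau2[:, None]), 0.0)
        sw = w.sum(axis=1)
    pooled = np.einsum("ij,ij->i", w, np.nan_to_num(E)) / sw
    pooled_se = np.sqrt(1.0 / sw)
    zval = pooled / pooled_se
    pval = 2 * stats.norm.sf(np.abs(zval))

    single = k == 1
    out = pd.DataFrame({"estimate": pooled, "se": pooled_se, "z": zval, "p": pval,
                        "Q": np.where(single, np.nan, Q),
                        "tau2": np.where(single, np.nan, tau2),
                        "k": k, "single_cohort": single}, index=all_cpgs)
    m = int((~single).sum())
    out["p_bonferroni"] = np.where(~single, np.minimum(out["p"] * m, 1.0), np.nan)
    out["dmp"] = ~single & (out["p_bonferroni"] < alpha)
    return out
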