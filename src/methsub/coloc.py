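"""Bayesian colocalization of two association signals in a region.

Per-SNP approximate Bayes factors (Wakefield) are combined over the five
hypotheses - H0 no association, H1/H2 one trait only, H3 two distinct
causal variants, H4 one shared causal variant - with per-SNP priors
p1, p2, p12, all sums performed in log space.  Colocalization is declared
when PP(H3) + PP(H4) exceeds 0.90 (the H4-only convention is available via
a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp


@dataclass
class ColocPosteriors:
    pp: np.ndarray  # PP0..PP4
    priors: tuple[float, float, float]
    n_snps: int

    def __getitem__(self, h: int) -> float:
        return float(self.pp[h])

    def as_dict(self) -> dict[str, float]:
        return {f"PP{h}": float(self.pp[h]) for h in range(5)}


def wakefield_labf(beta, se, W: float = 0.15) -> np.ndarray:
    """Log approximate Bayes factor for association at one SNP.

    labf = 0.5*log(se^2/(se^2 + W^2)) + 0.5*z^2*W^2/(se^2 + W^2), z = beta/se.
    ``W`` is the prior standard deviation of the true effect.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(se))):
        raise ValueError("beta/se must be finite")
    if np.any(se <= 0) or W < 0:
        raise ValueError("se must be positive and W non-negative")
    z = beta / se
    r = W ** 2 / (se ** 2 + W ** 2)
    return 0.5 * np.log1p(-r) + 0.5 * z ** 2 * r


def se_from_p_maf_n(p, maf, n) -> np.ndarray:
    """Reconstruct the effect standard error from p, allele frequency and n.

    Uses the quantitative-trait approximation var(beta) ~ 1/(2 n maf (1-maf)).
    """
    maf = np.asarray(maf, dtype=float)
    n = np.asarray(n, dtype=float)
    return np.sqrt(1.0 / (2.0 * n * maf * (1.0 - maf)))


def coloc_abf(stats1: pd.DataFrame, stats2: pd.DataFrame,
              p1: float = 1e-4, p2: float = 1e-4, p12: float = 1e-5,
              W: float = 0.15) -> ColocPosteriors:
    """Five-hypothesis colocalization posterior from two summary-stat tables.

    Each table needs columns snp, beta, se; SNPs are matched by id.  Sums
    over causal-variant configurations use log-sum-exp; the H3 double sum
    is the product of the marginal sums minus the diagonal, in log space.
    """
    merged = stats1.merge(stats2, on="snp", suffixes=("_1", "_2"))
    if len(merged) < 2:
        raise ValueError("need at least 2 shared SNPs")
    l1 = wakefield_labf(merged["beta_1"], merged["se_1"], W)
    l2 = wakefield_labf(merged["beta_2"], merged["se_2"], W)

    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # sum_{i != j} exp(l1_i + l2_j) = exp(s1)exp(s2) - exp(s12)
    both = logsumexp([s1 + s2, s12], b=[1.0, -1.0])

    lh = np.array([
        0.0,
        np.log(p1) + s1,
        np.log(p2) + s2,
        np.log(p1) + np.log(p2) + both,
        np.log(p12) + s12,
    ])
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocPosteriors(pp=pp, priors=(p1, p2, p12), n_snps=len(merged))


def colocalized(post: ColocPosteriors, threshold: float = 0.90,
                h4_only: bool = False) -> bool:
    """Apply the PP(H3)+PP(H4) > threshold decision rule."""
    if h4_only:
        return post[4] > threshold
    return post[3] + post[4] > threshold


def cis_mqtl_filter(assoc: pd.DataFrame, p_threshold: float = 1e-5) -> pd.DataFrame:
    """Pre-selection flag for cis-mQTL input SNPs (p below threshold)."""
    out = assoc.copy()
    out["cis_mqtl"] = out["p"] < p_threshold
    return out
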