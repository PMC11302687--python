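"""Single-causal-variant Bayesian colocalization via approximate Bayes factors.

For a region shared between a molecular-trait scan and a disease GWAS,
each variant gets a Wakefield log approximate Bayes factor per trait;
the five-hypothesis posterior (H0 no association, H1/H2 one trait only,
H3 two distinct causal variants, H4 one shared causal variant) follows
from prior per-variant probabilities p1, p2 and p12.  All sums run in
log space, so regions with |z| up to 100 do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

__all__ = ["ColocResult", "wakefield_labf", "coloc_abf"]

# Conventional effect-prior SDs implied by "default priors": log-odds
# scale for a case-control GWAS, and a fifth of a (z-scaled) trait SD.
PRIOR_SD_CC = 0.15
PRIOR_SD_QUANT = 0.2


@dataclass
class ColocResult:
    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    p1: float
    p2: float
    p12: float
    n_variants: int
    method: str = "single-causal"

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2,
                         self.pp_h3, self.pp_h4])


def wakefield_labf(beta: float | np.ndarray, se: float | np.ndarray,
                   prior_sd: float) -> np.ndarray:
    """Log approximate Bayes factor for one association statistic.

    labf = 0.5*log(se²/(se²+W)) + 0.5*z²*W/(se²+W), with W = prior_sd².
    Positive labf favours a real effect; at z = 0 the first (shrinkage)
    term makes the ABF a penalty, and as W → 0 the ABF → 1.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if not (np.isfinite(beta).all() and np.isfinite(se).all()):
        raise ValueError("non-finite beta/se")
    if (se <= 0).any():
        raise ValueError("se must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    W = prior_sd ** 2
    r = W / (se ** 2 + W)
    z2 = (beta / se) ** 2
    return 0.5 * np.log(1.0 - r) + 0.5 * z2 * r


def coloc_abf(labf_trait: np.ndarray, labf_gwas: np.ndarray,
              p1: float = 1e-4, p2: float = 1e-4, p12: float = 1e-5
              ) -> ColocResult:
    """Five-hypothesis colocalization posterior from per-variant log ABFs.

    The two vectors must be aligned on the same variant set.  Sums:
    H1 ∝ p1·Σᵢ ABF1ᵢ, H2 ∝ p2·Σⱼ ABF2ⱼ, H3 ∝ p1·p2·ΣΣ_{i≠j} ABF1ᵢABF2ⱼ,
    H4 ∝ p12·Σᵢ ABF1ᵢABF2ᵢ, normalized together with H0 ∝ 1.
    """
    l1 = np.asarray(labf_trait, dtype=float)
    l2 = np.asarray(labf_gwas, dtype=float)
    if l1.shape != l2.shape:
        raise ValueError("trait and GWAS log-ABF vectors differ in length "
                         "(variant sets not aligned)")
    m = l1.size
    if m < 2:
        raise ValueError("need at least 2 variants")
    for name, p in (("p1", p1), ("p2", p2), ("p12", p12)):
        if not 0 < p < 1:
            raise ValueError(f"{name} must be in (0, 1)")

    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    lh0 = 0.0
    lh1 = np.log(p1) + s1
    lh2 = np.log(p2) + s2
    # sum over i != j = (sum_i)(sum_j) - sum_i(i==j), kept in log space
    diff = s12 - (s1 + s2)
    if diff >= 0:  # numerically everything on the diagonal
        lh3 = -np.inf
    else:
        lh3 = np.log(p1) + np.log(p2) + s1 + s2 + np.log1p(-np.exp(diff))
    lh4 = np.log(p12) + s12

    lall = np.array([lh0, lh1, lh2, lh3, lh4])
    post = np.exp(lall - logsumexp(lall))
    post /= post.sum()
    return ColocResult(*post, p1=p1, p2=p2, p12=p12, n_variants=m)
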