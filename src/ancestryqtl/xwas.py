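"""Genetically imputed trait–disease association (PWAS/MWAS).

For each molecular feature, variant weights are trained on individual-
level data in ±1 Mb windows around its sentinel QTLs — elastic net
(mixing 0.5, penalty by 5-fold CV), the single best marginal variant
(top1), and ridge with a heritability-derived penalty (BLUP) — and the
model with the best cross-validated R² is refit on all data.  Features
first pass a heritability gate: a Haseman–Elston estimate of regional
SNP heritability must be positive.  The association test then combines
GWAS z-scores with the weights through a reference LD matrix:

    z_xwas = w'z / sqrt(w' R w)

which is the summary-statistic equivalent of regressing the disease on
the genetically predicted trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, ElasticNetCV, Ridge
from sklearn.model_selection import KFold

from .containers import GenotypeMatrix, GwasSumstats, parse_variant_id

__all__ = ["WeightModel", "XwasResult", "estimate_h2", "train_weight_model",
           "xwas_association", "bonferroni_gate", "align_alleles"]

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class WeightModel:
    feature: str
    variants: list[str]
    weights: np.ndarray
    model: str                 # enet | top1 | blup
    cv_r2: float
    h2: float
    usable: bool

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.model == "top1" and np.count_nonzero(self.weights) > 1:
            raise ValueError("top1 model must have exactly one nonzero weight")


@dataclass
class XwasResult:
    feature: str
    z_xwas: float
    p: float
    n_variants_used: int
    n_variants_dropped: int = 0


def estimate_h2(geno_region: np.ndarray, trait: np.ndarray) -> float:
    """Haseman–Elston regression estimate of regional SNP heritability.

    Regresses off-diagonal products of the standardized trait on the
    corresponding genetic-relatedness entries; the closed-form slope is
    sum(A_ij y_i y_j) / sum(A_ij^2) over i<j.  May legitimately be
    negative for a non-genetic trait — the caller uses only the sign.
    """
    G = np.asarray(geno_region, dtype=float)
    y = np.asarray(trait, dtype=float)
    n, m = G.shape
    if m < 2:
        raise ValueError("need at least 2 variants")
    if n < 50:
        raise ValueError("need at least 50 samples")
    if np.nanstd(y) == 0:
        raise ValueError("constant trait")
    obs = np.isfinite(y)
    G, y = G[obs], y[obs]
    y = (y - y.mean()) / y.std()
    sd = G.std(axis=0)
    keep = sd > 0
    Gs = (G[:, keep] - G[:, keep].mean(axis=0)) / sd[keep]
    A = (Gs @ Gs.T) / keep.sum()
    iu = np.triu_indices(len(y), k=1)
    a = A[iu]
    yy = np.outer(y, y)[iu]
    denom = (a ** 2).sum()
    if denom == 0:
        raise ValueError("degenerate relatedness matrix")
    return float((a * yy).sum() / denom)


def _cv_r2(pred_fn, G: np.ndarray, y: np.ndarray, folds: int,
           rng_seed: int) -> float:
    """Out-of-fold R² of a fit/predict closure."""
    kf = KFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    pred = np.full(len(y), np.nan)
    for tr, te in kf.split(G):
        pred[te] = pred_fn(G[tr], y[tr], G[te])
    ss_res = ((y - pred) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


def train_weight_model(geno_region: GenotypeMatrix | np.ndarray,
                       trait: np.ndarray,
                       feature: str = "feature",
                       folds: int = 5, seed: int = 0,
                       h2: Optional[float] = None) -> WeightModel:
    """Fit enet/top1/blup weights and keep the best CV performer.

    The heritability gate runs first (unless ``h2`` is supplied): a
    non-positive Haseman–Elston estimate marks the model unusable with
    zero weights.  A winner whose CV R² is not positive is likewise
    flagged unusable.  Deterministic for a fixed seed.
    """
    if isinstance(geno_region, GenotypeMatrix):
        variant_ids = geno_region.variant_ids
        G = geno_region.dosages
    else:
        G = np.asarray(geno_region, dtype=float)
        variant_ids = [f"v{j}" for j in range(G.shape[1])]
    y = np.asarray(trait, dtype=float)
    obs = np.isfinite(y)
    G, y = G[obs], y[obs]
    m = G.shape[1]

    if h2 is None:
        h2 = estimate_h2(G, y)
    if h2 <= 0:
        return WeightModel(feature=feature, variants=list(variant_ids),
                           weights=np.zeros(m), model="none",
                           cv_r2=0.0, h2=h2, usable=False)

    y_std = (y - y.mean()) / y.std()
    seed = int(seed) % (2 ** 31 - 1)

    def fit_enet(Gtr, ytr, Gte):
        cv = ElasticNetCV(l1_ratio=0.5, cv=folds, random_state=seed,
                          alphas=30, max_iter=5000)
        cv.fit(Gtr, ytr)
        return cv.predict(Gte)

    def fit_top1(Gtr, ytr, Gte):
        j, b, a = _best_marginal(Gtr, ytr)
        return a + b * Gte[:, j]

    h2c = min(max(h2, 0.01), 0.99)
    lam = m * (1.0 - h2c) / h2c   # ridge penalty implied by the heritability

    def fit_blup(Gtr, ytr, Gte):
        r = Ridge(alpha=lam)
        r.fit(Gtr, ytr)
        return r.predict(Gte)

    scores = {
        "enet": _cv_r2(fit_enet, G, y_std, folds, seed),
        "top1": _cv_r2(fit_top1, G, y_std, folds, seed + 1),
        "blup": _cv_r2(fit_blup, G, y_std, folds, seed + 2),
    }
    best = max(scores, key=lambda k: scores[k])
    cv_r2 = scores[best]
    if cv_r2 <= 0:
        return WeightModel(feature=feature, variants=list(variant_ids),
                           weights=np.zeros(m), model=best,
                           cv_r2=cv_r2, h2=h2, usable=False)

    # refit the winner on all data
    if best == "enet":
        cvm = ElasticNetCV(l1_ratio=0.5, cv=folds, random_state=seed,
                           alphas=30, max_iter=5000)
        cvm.fit(G, y_std)
        w = ElasticNet(alpha=cvm.alpha_, l1_ratio=0.5, max_iter=5000)
        w.fit(G, y_std)
        weights = w.coef_
    elif best == "top1":
        j, b, _ = _best_marginal(G, y_std)
        weights = np.zeros(m)
        weights[j] = b
    else:
        r = Ridge(alpha=lam)
        r.fit(G, y_std)
        weights = r.coef_

    return WeightModel(feature=feature, variants=list(variant_ids),
                       weights=weights, model=best, cv_r2=cv_r2, h2=h2,
                       usable=True)


def _best_marginal(G: np.ndarray, y: np.ndarray) -> tuple[int, float, float]:
    """Index, slope and intercept of the best single-variant regression."""
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    gg = (Gc ** 2).sum(axis=0)
    gg_safe = np.where(gg > 0, gg, np.inf)
    b = (Gc.T @ yc) / gg_safe
    r2 = b ** 2 * gg_safe
    j = int(np.argmax(np.where(np.isfinite(r2), r2, -np.inf)))
    slope = b[j]
    intercept = y.mean() - slope * G[:, j].mean()
    return j, float(slope), float(intercept)


def align_alleles(weight_variants: Sequence[str],
                  gwas: GwasSumstats) -> tuple[list[int], np.ndarray, list[str]]:
    """Match weight variants to GWAS rows on chr:pos:ref:alt.

    Returns (kept weight indices, signed GWAS z for them, dropped ids).
    Swapped ref/alt flips the z sign; strand-ambiguous A/T and C/G
    variants, and variants absent from the GWAS, are dropped.
    """
    tab = gwas.table.set_index("variant")
    zvals = gwas.table.set_index("variant")["beta"] / gwas.table.set_index("variant")["se"]
    kept_idx: list[int] = []
    kept_z: list[float] = []
    dropped: list[str] = []
    for i, vid in enumerate(weight_variants):
        chrom, pos, ref, alt = parse_variant_id(vid)
        if (ref, alt) in _AMBIGUOUS:
            dropped.append(vid)
            continue
        if vid in tab.index:
            kept_idx.append(i)
            kept_z.append(float(zvals.loc[vid]))
            continue
        flipped = f"{chrom}:{pos}:{alt}:{ref}"
        if flipped in tab.index:
            kept_idx.append(i)
            kept_z.append(-float(zvals.loc[flipped]))
            continue
        dropped.append(vid)
    return kept_idx, np.array(kept_z), dropped


def xwas_association(model: WeightModel, gwas: GwasSumstats,
                     ld_ref: np.ndarray) -> XwasResult:
    """FUSION-style summary association of a weighted trait with disease.

    ``ld_ref`` is the variant correlation matrix over ``model.variants``
    (in-sample reference LD).  z_xwas = w'z / sqrt(w'Rw); invariant to
    rescaling the weights.
    """
    R = np.asarray(ld_ref, dtype=float)
    if R.shape != (len(model.variants), len(model.variants)):
        raise ValueError("LD matrix does not match the weight variant set")
    idx, z, dropped = align_alleles(model.variants, gwas)
    if len(idx) == 0:
        raise ValueError(f"no weight variants of {model.feature} found in the GWAS")
    w = model.weights[idx]
    Rk = R[np.ix_(idx, idx)]
    denom2 = float(w @ Rk @ w)
    if denom2 <= 1e-8:
        raise ValueError(f"degenerate weights for {model.feature}: w'Rw = {denom2:g}")
    z_xwas = float(w @ z) / np.sqrt(denom2)
    p = float(2.0 * stats.norm.sf(abs(z_xwas)))
    return XwasResult(feature=model.feature, z_xwas=z_xwas, p=p,
                      n_variants_used=len(idx), n_variants_dropped=len(dropped))


def bonferroni_gate(results: Sequence[XwasResult], n_models: int
                    ) -> list[XwasResult]:
    """Keep results with p strictly below 0.05 / n_models."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    alpha = 0.05 / n_models
    return [r for r in results if r.p < alpha]
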