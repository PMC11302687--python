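"""Two-sample Mendelian randomization of molecular traits on disease.

Instruments are study-wide-significant QTL variants that survive three
filters — exclusion of pleiotropic LD blocks (blocks associated with
many features, with an escape clause for variants in linkage
equilibrium with the block's sentinel), greedy LD clumping by p-value,
and a per-variant F statistic above 10.  One instrument gives the Wald
ratio; several give the inverse-variance-weighted (IVW) estimate,
equivalent to weighted least squares through the origin.  Feature-level
multiplicity is controlled by Benjamini–Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["InstrumentSet", "MRResult", "select_instruments",
           "wald_ratio", "ivw", "mr_feature", "bh_fdr"]


@dataclass
class InstrumentSet:
    feature: str
    table: pd.DataFrame          # variant, beta_exp, se_exp, beta_out, se_out, F
    exclusions: pd.DataFrame     # variant, reason

    @property
    def n(self) -> int:
        return len(self.table)


@dataclass
class MRResult:
    feature: str
    beta_mr: float
    se: float
    p: float
    method: str                  # wald | ivw
    n_instruments: int
    fdr_q: float = np.nan


def select_instruments(qtls: pd.DataFrame,
                       gwas: pd.DataFrame,
                       ld_ref: Optional[pd.DataFrame] = None,
                       pleiotropic_blocks: Sequence[int] = (),
                       block_sentinels: Optional[dict[int, str]] = None,
                       clump_r2: float = 0.001,
                       f_min: float = 10.0,
                       pleio_escape_r2: float = 0.8,
                       feature: str = "") -> InstrumentSet:
    """Filter a feature's QTLs down to valid MR instruments.

    ``qtls``: study-wide-significant rows for one feature with columns
    variant, beta, se, p, ld_block.  ``gwas``: outcome summary table
    with variant, beta, se.  ``ld_ref``: symmetric r² DataFrame indexed
    by variant id (needed for clumping and the pleiotropy escape; if
    absent, instruments are assumed independent).

    Filters, in order: (1) variants inside pleiotropic blocks are
    excluded unless their r² with the block's sentinel is below
    ``pleio_escape_r2``; (2) greedy clump by ascending p at
    ``clump_r2``; (3) F = (beta/se)² must exceed ``f_min``; (4) the
    variant must be present in the outcome GWAS.
    """
    exclusions = []
    df = qtls.copy().sort_values("p", kind="mergesort").reset_index(drop=True)

    def r2(a: str, b: str) -> float:
        # ld_ref holds correlations r; clumping and escape work on r^2
        if ld_ref is None or a not in ld_ref.index or b not in ld_ref.columns:
            return 0.0
        return float(ld_ref.loc[a, b]) ** 2

    pleio = set(pleiotropic_blocks)
    keep_rows = []
    for _, row in df.iterrows():
        blk = row.get("ld_block", -1)
        if blk in pleio:
            sent = (block_sentinels or {}).get(blk)
            if sent is None or r2(row["variant"], sent) >= pleio_escape_r2:
                exclusions.append(dict(variant=row["variant"], reason="pleiotropic"))
                continue
        keep_rows.append(row)

    clumped: list = []
    for row in keep_rows:   # already in ascending-p order
        if any(r2(row["variant"], kept["variant"]) > clump_r2 for kept in clumped):
            exclusions.append(dict(variant=row["variant"], reason="ld_clump"))
            continue
        clumped.append(row)

    gwas_idx = gwas.set_index("variant")
    rows = []
    for row in clumped:
        F = (row["beta"] / row["se"]) ** 2
        if F <= f_min:
            exclusions.append(dict(variant=row["variant"], reason="weak_F"))
            continue
        if row["variant"] not in gwas_idx.index:
            exclusions.append(dict(variant=row["variant"], reason="missing_in_outcome"))
            continue
        out = gwas_idx.loc[row["variant"]]
        rows.append(dict(variant=row["variant"],
                         beta_exp=row["beta"], se_exp=row["se"],
                         beta_out=float(out["beta"]), se_out=float(out["se"]),
                         F=F))
    return InstrumentSet(
        feature=feature,
        table=pd.DataFrame(rows, columns=["variant", "beta_exp", "se_exp",
                                          "beta_out", "se_out", "F"]),
        exclusions=pd.DataFrame(exclusions, columns=["variant", "reason"]))


def wald_ratio(beta_exp: float, se_exp: float,
               beta_out: float, se_out: float,
               second_order: bool = False) -> tuple[float, float]:
    """Single-instrument causal-effect estimate beta_out/beta_exp.

    First-order delta-method SE by default (se_out/|beta_exp|); the
    second-order correction adds the exposure-uncertainty term.
    """
    if beta_exp == 0:
        raise ValueError("beta_exp must be nonzero for a Wald ratio")
    b = beta_out / beta_exp
    if second_order:
        se = np.sqrt(se_out ** 2 / beta_exp ** 2
                     + beta_out ** 2 * se_exp ** 2 / beta_exp ** 4)
    else:
        se = se_out / abs(beta_exp)
    return float(b), float(se)


def ivw(ratios: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Inverse-variance-weighted combination of per-instrument ratios.

    estimate = Σ wᵢbᵢ / Σ wᵢ with wᵢ = seᵢ⁻²; se = (Σ wᵢ)^(-1/2).
    With one instrument this reduces to that instrument's Wald ratio.
    """
    b = np.array([r[0] for r in ratios], dtype=float)
    s = np.array([r[1] for r in ratios], dtype=float)
    if len(b) == 0:
        raise ValueError("no instruments")
    if (s <= 0).any():
        raise ValueError("instrument SEs must be positive")
    w = s ** -2
    est = float((w * b).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    return est, se


def mr_feature(instruments: InstrumentSet) -> Optional[MRResult]:
    """Wald ratio (1 instrument) or IVW (≥2) for one feature.

    Returns None when the instrument set is empty — reported upstream
    as "no valid instruments", not an error.
    """
    tab = instruments.table
    if len(tab) == 0:
        return None
    ratios = [wald_ratio(r.beta_exp, r.se_exp, r.beta_out, r.se_out)
              for r in tab.itertuples()]
    if len(ratios) == 1:
        beta, se = ratios[0]
        method = "wald"
    else:
        beta, se = ivw(ratios)
        method = "ivw"
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return MRResult(feature=instruments.feature, beta_mr=beta, se=se, p=p,
                    method=method, n_instruments=len(ratios))


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return np.array([])
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
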