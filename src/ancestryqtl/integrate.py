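"""Evidence integration and external replication.

A feature is nominated as a disease effector when it passes all three
summary-level analyses — XWAS (Bonferroni), colocalization (PP.H4 >
0.8) and MR (FDR < 0.05).  A complementary combined posterior treats
the colocalization probability as a prior (floored so coloc can never
veto outright) and the XWAS z as a Bayes factor.  Replication against
an external QTL table assigns each internal finding exactly one of six
categories based on the best matching variant or LD proxy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["EvidenceRow", "triple_evidence", "intact_posterior",
           "ReplicationCall", "replication_categorize", "REPLICATION_CATEGORIES"]


@dataclass
class EvidenceRow:
    feature: str
    ancestry: str
    xwas_pass: Optional[bool]
    coloc_pass: Optional[bool]
    mr_pass: Optional[bool]
    intact_pp: Optional[float]
    nominated: bool


def triple_evidence(xwas: pd.DataFrame, coloc: pd.DataFrame, mr: pd.DataFrame,
                    ancestry: str = "",
                    xwas_alpha: float | None = None,
                    pp_h4_min: float = 0.8,
                    fdr_max: float = 0.05,
                    intact_floor: float = 0.05) -> pd.DataFrame:
    """Join the three analyses by feature and apply the triple rule.

    Inputs (one row per feature): ``xwas`` with z_xwas and p, ``coloc``
    with pp_h4, ``mr`` with fdr_q.  ``xwas_alpha`` defaults to
    0.05 / (number of XWAS models tested).  A feature missing from an
    analysis keeps that flag unset (pandas NA) and cannot be nominated.
    Output rows are ordered by feature id.
    """
    for name, df in (("xwas", xwas), ("coloc", coloc), ("mr", mr)):
        if not df.empty and df["feature"].duplicated().any():
            dups = df["feature"][df["feature"].duplicated()].tolist()
            raise ValueError(f"duplicate feature keys in {name}: {dups}")
    if xwas_alpha is None:
        xwas_alpha = 0.05 / max(len(xwas), 1)

    feats = sorted(set(xwas["feature"]) | set(coloc["feature"]) | set(mr["feature"]))
    xi = xwas.set_index("feature")
    ci = coloc.set_index("feature")
    mi = mr.set_index("feature")
    rows = []
    for f in feats:
        xp = bool(xi.loc[f, "p"] < xwas_alpha) if f in xi.index else pd.NA
        cp = bool(ci.loc[f, "pp_h4"] > pp_h4_min) if f in ci.index else pd.NA
        mp = bool(mi.loc[f, "fdr_q"] < fdr_max) if f in mi.index else pd.NA
        if f in xi.index and f in ci.index:
            ipp = intact_posterior(float(ci.loc[f, "pp_h4"]),
                                   float(xi.loc[f, "z_xwas"]),
                                   prior_floor=intact_floor)
        else:
            ipp = pd.NA
        nominated = (xp is True) and (cp is True) and (mp is True)
        rows.append(dict(feature=f, ancestry=ancestry, xwas_pass=xp,
                         coloc_pass=cp, mr_pass=mp, intact_pp=ipp,
                         nominated=nominated))
    return pd.DataFrame(rows, columns=["feature", "ancestry", "xwas_pass",
                                       "coloc_pass", "mr_pass", "intact_pp",
                                       "nominated"])


def intact_posterior(pp_h4: float, z_xwas: float,
                     prior_floor: float = 0.05) -> float:
    """Combined causal posterior from colocalization and XWAS evidence.

    Linear-truncation prior π = max(pp_h4, floor); the XWAS z becomes a
    unit-information Wakefield-style Bayes factor BF = exp(z²/4)/√2;
    posterior = BF·π / (BF·π + 1 − π).  Monotone in both inputs; with
    pp_h4 = 1 the prior is degenerate and the posterior is 1.
    """
    if not 0.0 <= pp_h4 <= 1.0:
        raise ValueError("pp_h4 must be in [0, 1]")
    pi = max(pp_h4, prior_floor)
    if pi >= 1.0:
        return 1.0
    # W = 1 (unit information) in labf = -0.5*log(1+W) + z^2/2 * W/(1+W)
    log_bf = -0.5 * np.log(2.0) + 0.25 * z_xwas ** 2
    log_odds = log_bf + np.log(pi) - np.log1p(-pi)
    return float(1.0 / (1.0 + np.exp(-log_odds)))


REPLICATION_CATEGORIES = ("validated", "known", "replicated",
                          "not_replicated", "no_proxy", "no_feature")


@dataclass(frozen=True)
class ReplicationCall:
    feature: str
    variant: str
    study: str
    category: str
    matched_variant: Optional[str] = None
    external_p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.category not in REPLICATION_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def replication_categorize(feature: str, variant: str,
                           external: pd.DataFrame,
                           ld_r2: Optional[pd.DataFrame] = None,
                           study: str = "external",
                           proxy_r2: float = 0.8,
                           validated_p: float = 5e-11,
                           known_p: float = 5e-8,
                           nominal_p: float = 5e-2) -> ReplicationCall:
    """Assign one of six replication categories to a feature-variant pair.

    ``external`` columns: feature, variant, p.  ``ld_r2`` is a symmetric
    r² DataFrame indexed by variant id; the pair's variant itself counts
    as a proxy with r² = 1.  Among multiple proxies the best match is
    the smallest external p, ties broken by the higher r².
    """
    ext = external[external["feature"] == feature]
    if ext.empty:
        return ReplicationCall(feature, variant, study, "no_feature")

    cands = []
    for row in ext.itertuples():
        if row.variant == variant:
            r2 = 1.0
        elif (ld_r2 is not None and variant in ld_r2.index
              and row.variant in ld_r2.columns):
            r2 = float(ld_r2.loc[variant, row.variant])
        else:
            r2 = 0.0
        if r2 >= proxy_r2:
            cands.append((float(row.p), -r2, row.variant))
    if not cands:
        return ReplicationCall(feature, variant, study, "no_proxy")

    p, neg_r2, best_variant = min(cands)
    if p < validated_p:
        cat = "validated"
    elif p < known_p:
        cat = "known"
    elif p < nominal_p:
        cat = "replicated"
    else:
        cat = "not_replicated"
    return ReplicationCall(feature, variant, study, cat,
                           matched_variant=best_variant, external_p=p)
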