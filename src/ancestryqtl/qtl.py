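"""Per-ancestry additive-model QTL scan and post-processing.

The scan regresses each (transformed) molecular trait on minor-allele
dosage plus covariates by ordinary least squares, one variant at a
time, and reports the dosage term's beta, SE, t-based two-sided p and
Z = beta/SE.  Downstream helpers derive the study-wide significance
threshold (genome-wide 5e-8 divided by the number of principal
components explaining 95% of trait variance), label cis/trans for
proteins (±1 Mb of the coding-gene start), prune features inflated
across many chromosomes, and summarize pleiotropy per LD block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, LDBlock, ThresholdSpec, TraitMatrix

__all__ = [
    "ScanResult",
    "fit_additive_scan",
    "count_independent_components",
    "derive_study_threshold",
    "round_sig",
    "classify_cis_trans",
    "annotate_cis_trans",
    "filter_inflated_features",
    "assign_ld_blocks_and_hotspots",
    "select_sentinels",
]

SCAN_COLUMNS = ["feature", "variant", "chrom", "pos", "ref", "alt",
                "beta", "se", "z", "p", "n", "maf", "callrate"]


@dataclass
class ScanResult:
    """Association table plus the bookkeeping the scan is obliged to keep."""

    table: pd.DataFrame
    skipped: pd.DataFrame      # feature/variant pairs with <30 complete obs
    flagged: pd.DataFrame      # rank-deficient or degenerate designs
    transform: str = "none"
    ancestry: str = ""


def _transform_traits(values: np.ndarray, transform: str) -> np.ndarray:
    """Apply the per-feature normalization the scan assumes.

    ``log10+zscale``: log10 then z-score (proteomics convention);
    ``median-log10``: divide by the feature median, then log10
    (metabolomics convention); ``none``: already normalized.
    """
    v = values.copy()
    if transform == "none":
        return v
    if transform == "log10+zscale":
        if np.nanmin(v) <= 0:
            raise ValueError("log10 transform requires positive values")
        v = np.log10(v)
        mu = np.nanmean(v, axis=0)
        sd = np.nanstd(v, axis=0, ddof=1)
        sd[sd == 0] = 1.0
        return (v - mu) / sd
    if transform == "median-log10":
        if np.nanmin(v) <= 0:
            raise ValueError("log10 transform requires positive values")
        med = np.nanmedian(v, axis=0)
        return np.log10(v / med)
    raise ValueError(f"unknown transform {transform!r}")


def _design_matrix(covariates: pd.DataFrame, samples: Sequence[str]) -> np.ndarray:
    """Intercept + covariates, with batch one-hot encoded (n−1 dummies)."""
    cov = covariates.set_index("sample").loc[list(samples)]
    cols = [np.ones(len(cov))]
    for c in cov.columns:
        if c == "batch" or not np.issubdtype(cov[c].dtype, np.number):
            dummies = pd.get_dummies(cov[c].astype("category"), drop_first=True)
            for dc in dummies.columns:
                cols.append(dummies[dc].to_numpy(dtype=float))
        else:
            cols.append(cov[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def fit_additive_scan(geno: GenotypeMatrix, traits: TraitMatrix,
                      covariates: Optional[pd.DataFrame] = None,
                      transform: str = "none",
                      min_obs: int = 30) -> ScanResult:
    """OLS scan of every variant × feature pair.

    Equivalent to fitting ``trait ~ dosage + covariates`` per pair; the
    implementation residualizes trait and dosages on the covariates
    (Frisch–Waugh–Lovell), which reproduces the full OLS estimate, SE
    and t-test exactly.  Pairs with fewer than ``min_obs`` complete
    observations are skipped and reported; rank-deficient designs are
    flagged rather than silently dropped.
    """
    if list(geno.samples) != list(traits.samples):
        raise ValueError("genotype and trait samples are not aligned")
    if covariates is not None and "sample" not in covariates.columns:
        raise ValueError("covariate table needs a 'sample' column")

    values = _transform_traits(traits.values, transform)
    n_all = geno.n_samples
    if covariates is not None:
        X_all = _design_matrix(covariates, geno.samples)
    else:
        X_all = np.ones((n_all, 1))

    chroms = np.array([v.chrom for v in geno.variants])
    poss = np.array([v.pos for v in geno.variants])
    refs = np.array([v.ref for v in geno.variants])
    alts = np.array([v.alt for v in geno.variants])
    vids = np.array(geno.variant_ids)
    col_maf = geno.column_maf()

    rows, skipped, flagged = [], [], []
    for j, fid in enumerate(traits.feature_ids):
        y = values[:, j]
        obs = np.isfinite(y)
        n = int(obs.sum())
        if n < min_obs:
            skipped.append(dict(feature=fid, n_obs=n,
                                reason=f"fewer than {min_obs} complete observations"))
            continue
        X = X_all[obs]
        if np.linalg.matrix_rank(X) < X.shape[1]:
            flagged.append(dict(feature=fid, reason="rank-deficient covariate design"))
            continue
        Q, _ = np.linalg.qr(X)
        yv = y[obs]
        y_res = yv - Q @ (Q.T @ yv)
        G = geno.dosages[obs]
        G_res = G - Q @ (Q.T @ G)

        gg = (G_res ** 2).sum(axis=0)
        dof = n - X.shape[1] - 1
        good = gg > 1e-12
        if (~good).any():
            for vid in vids[~good]:
                flagged.append(dict(feature=fid, variant=vid,
                                    reason="degenerate dosage after covariate projection"))
        beta = np.full(len(vids), np.nan)
        beta[good] = (G_res[:, good].T @ y_res) / gg[good]
        rss = (y_res @ y_res) - beta ** 2 * gg
        sigma2 = rss / dof
        se = np.sqrt(np.maximum(sigma2, 0.0) / np.where(good, gg, np.nan))
        with np.errstate(invalid="ignore", divide="ignore"):
            t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), dof)
        p = np.clip(p, np.finfo(float).tiny, 1.0)

        sel = good
        rows.append(pd.DataFrame({
            "feature": fid, "variant": vids[sel], "chrom": chroms[sel],
            "pos": poss[sel], "ref": refs[sel], "alt": alts[sel],
            "beta": beta[sel], "se": se[sel], "z": t[sel], "p": p[sel],
            "n": n, "maf": col_maf[sel], "callrate": 1.0,
        }))

    table = (pd.concat(rows, ignore_index=True) if rows
             else pd.DataFrame(columns=SCAN_COLUMNS))
    return ScanResult(table=table,
                      skipped=pd.DataFrame(skipped, columns=["feature", "n_obs", "reason"]),
                      flagged=pd.DataFrame(flagged, columns=["feature", "variant", "reason"]),
                      transform=transform, ancestry=geno.ancestry)


def count_independent_components(values: np.ndarray | TraitMatrix,
                                 var_frac: float = 0.95) -> int:
    """Smallest number of principal components explaining ``var_frac``.

    Defines the effective number of independent molecular features used
    as the Bonferroni denominator of the study-wide threshold.
    """
    if isinstance(values, TraitMatrix):
        values = values.values
    X = np.asarray(values, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("component counting needs a complete (imputed) matrix")
    if not 0.0 < var_frac <= 1.0:
        raise ValueError("var_frac must be in (0, 1]")
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    ev = s ** 2
    tot = ev.sum()
    if tot == 0:
        return 1
    if var_frac == 1.0:
        tol = ev.max() * max(X.shape) * np.finfo(float).eps
        return int((ev > tol).sum())
    frac = np.cumsum(ev) / tot
    return int(np.searchsorted(frac, var_frac - 1e-12) + 1)


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (reporting convention)."""
    if x == 0 or not np.isfinite(x):
        return x
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + digits - 1)


def derive_study_threshold(n_components: int,
                           genome_wide: float = 5e-8) -> ThresholdSpec:
    """Study-wide p threshold = genome-wide / number of independent features."""
    if n_components < 1:
        raise ValueError("n_components must be a positive count")
    if genome_wide <= 0:
        raise ValueError("genome_wide threshold must be positive")
    return ThresholdSpec(genome_wide=genome_wide, n_components=int(n_components),
                         study_wide=genome_wide / n_components)


def classify_cis_trans(variant_chrom: str, variant_pos: int,
                       gene_chrom: str, gene_start: int,
                       window: int = 1_000_000) -> str:
    """cis iff same chromosome and |pos − gene start| ≤ window (inclusive)."""
    if gene_chrom == variant_chrom and abs(int(variant_pos) - int(gene_start)) <= window:
        return "cis"
    return "trans"


def annotate_cis_trans(table: pd.DataFrame, features: pd.DataFrame,
                       window: int = 1_000_000) -> pd.DataFrame:
    """Add a ``cis_trans`` column; defined for protein features only."""
    meta = features.set_index("id")
    kinds = meta.loc[table["feature"], "kind"].to_numpy()
    if (kinds == "metabolite").any():
        raise ValueError("cis/trans is defined only for protein features")
    gene_chrom = meta.loc[table["feature"], "chrom"].to_numpy()
    gene_start = meta.loc[table["feature"], "gene_start"].to_numpy(dtype=float)
    same = table["chrom"].to_numpy() == gene_chrom
    near = np.abs(table["pos"].to_numpy() - gene_start) <= window
    out = table.copy()
    out["cis_trans"] = np.where(same & near, "cis", "trans")
    return out


def filter_inflated_features(records: pd.DataFrame, chrom_limit: int,
                             maf_floor: float = 0.05,
                             callrate_floor: float = 0.97
                             ) -> tuple[pd.DataFrame, list[str], pd.DataFrame]:
    """Prune features whose significant hits span too many chromosomes.

    For each feature with significant hits on more than ``chrom_limit``
    chromosomes, first drop its hits at low-quality variants
    (MAF < ``maf_floor`` or call rate < ``callrate_floor``); a feature
    still inflated after the rescue is removed entirely.  ``records``
    must carry ``sig``, ``maf`` and ``callrate`` columns.
    """
    if records.empty:
        return records.copy(), [], pd.DataFrame(columns=["feature", "action"])
    out = records.copy()
    removed_features: list[str] = []
    actions = []
    for fid, grp in records[records["sig"]].groupby("feature"):
        nchrom = grp["chrom"].nunique()
        if nchrom <= chrom_limit:
            continue
        lowq = (grp["maf"] < maf_floor) | (grp["callrate"] < callrate_floor)
        rescue_drop = grp.index[lowq]
        remaining = grp.drop(rescue_drop)
        if remaining["chrom"].nunique() > chrom_limit:
            removed_features.append(fid)
            out = out[out["feature"] != fid]
            actions.append(dict(feature=fid, action="feature_removed"))
        else:
            out = out.drop(rescue_drop)
            actions.append(dict(feature=fid,
                                action=f"pruned_{len(rescue_drop)}_low_quality_hits"))
    return (out.reset_index(drop=True), removed_features,
            pd.DataFrame(actions, columns=["feature", "action"]))


def assign_ld_blocks_and_hotspots(records: pd.DataFrame,
                                  blocks: Sequence[LDBlock]
                                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary-search LD-block assignment plus per-block pleiotropy counts.

    Variants falling outside every block get the sentinel index −1
    ("unblocked") and are counted separately in the hotspot table.
    Blocks are half-open [start, end).
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {b.chrom for b in blocks}:
        bs = sorted((b for b in blocks if b.chrom == chrom), key=lambda b: b.start)
        starts = np.array([b.start for b in bs])
        ends = np.array([b.end for b in bs])
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping LD blocks on {chrom}")
        by_chrom[chrom] = (starts, ends, np.array([b.index for b in bs]))

    out = records.copy()
    assigned = np.full(len(out), -1, dtype=int)
    for chrom, sel in out.groupby("chrom").groups.items():
        if chrom not in by_chrom:
            continue
        starts, ends, idxs = by_chrom[chrom]
        pos = out.loc[sel, "pos"].to_numpy()
        k = np.searchsorted(starts, pos, side="right") - 1
        ok = (k >= 0) & (pos < ends[np.clip(k, 0, len(ends) - 1)])
        vals = np.where(ok, idxs[np.clip(k, 0, len(idxs) - 1)], -1)
        assigned[out.index.get_indexer(sel)] = vals
    out["ld_block"] = assigned

    sig = out[out["sig"]] if "sig" in out.columns else out
    counts = (sig.groupby("ld_block")["feature"].nunique()
              .sort_values(ascending=False).rename("n_features").reset_index())
    return out, counts


def select_sentinels(records: pd.DataFrame) -> pd.DataFrame:
    """One sentinel per feature × LD block: smallest p, ties by |z| then id."""
    df = records.copy()
    df["_absz"] = -df["z"].abs()
    df = df.sort_values(["feature", "ld_block", "p", "_absz", "variant"],
                        kind="mergesort")
    sent = df.groupby(["feature", "ld_block"], as_index=False).head(1)
    return sent.drop(columns="_absz").reset_index(drop=True)
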