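"""Order-preserving proteomics and metabolomics QC.

The proteomics pipeline is seven steps (platform filters, IQR outlier
masking, two-stage call-rate filtering of analytes and samples,
back-transformation, target-annotation filtering); the metabolomics
pipeline is eleven (volume normalization, sample/metabolite
missingness, batch-missingness association, minimum-value imputation
restricted to non-xenobiotics, non-informative removal, IQR outliers,
minimum data points, PCA sample outliers, batch-median alignment,
back-transformation).  Every step logs exactly what it removed so the
report telescopes: before − removed = after at each step.

Call rate is the fraction of non-missing entries; comparisons are
strict (<), so items at exactly the threshold are kept.  Platform-level
thresholds that live in vendor documentation (limit of detection, scale
factors, replicate CVs, the exact batch-missingness test) are exposed
as configurable hooks with conservative defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import TraitMatrix

__all__ = ["QcConfig", "QcReport", "iqr_outlier_mask",
           "qc_proteomics", "qc_metabolomics"]


@dataclass
class QcConfig:
    analyte_callrate_stage1: float = 0.65
    analyte_callrate_stage2: float = 0.85
    sample_callrate_stage1: float = 0.65
    sample_callrate_stage2: float = 0.85
    iqr_k: float = 1.5
    min_datapoints: int = 50
    cv_max: float = 0.15          # replicate CV hook (needs replicate labels)
    fisher_p: float = 1e-3        # batch-missingness association cutoff
    pca_k: float = 3.0            # sample outlier fence in SDs on PC1/PC2
    transform: str = "none"       # forward transform the input sits on: none|log10|log
    align_batches: bool = True

    def __post_init__(self) -> None:
        for name in ("analyte_callrate_stage1", "analyte_callrate_stage2",
                     "sample_callrate_stage1", "sample_callrate_stage2"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.iqr_k <= 0:
            raise ValueError("iqr_k must be > 0")
        if self.transform not in ("none", "log10", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class QcStep:
    name: str
    removed_features: list[str] = field(default_factory=list)
    removed_samples: list[str] = field(default_factory=list)
    masked_cells: int = 0
    shape_before: tuple[int, int] = (0, 0)
    shape_after: tuple[int, int] = (0, 0)
    reason: str = ""


@dataclass
class QcReport:
    steps: list[QcStep] = field(default_factory=list)

    @property
    def final_shape(self) -> tuple[int, int]:
        return self.steps[-1].shape_after if self.steps else (0, 0)

    def telescopes(self) -> bool:
        """Counts must chain exactly: after = before − removed, step to step."""
        prev = None
        for s in self.steps:
            n0, m0 = s.shape_before
            n1, m1 = s.shape_after
            if n1 != n0 - len(s.removed_samples) or m1 != m0 - len(s.removed_features):
                return False
            if prev is not None and s.shape_before != prev:
                return False
            prev = s.shape_after
        return True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "step": s.name,
            "n_features_removed": len(s.removed_features),
            "n_samples_removed": len(s.removed_samples),
            "cells_masked": s.masked_cells,
            "shape_before": f"{s.shape_before[0]}x{s.shape_before[1]}",
            "shape_after": f"{s.shape_after[0]}x{s.shape_after[1]}",
            "reason": s.reason,
        } for s in self.steps])


def iqr_outlier_mask(values: np.ndarray, k: float = 1.5) -> np.ndarray:
    """True where a value lies beyond Q1 − k·IQR or Q3 + k·IQR.

    Quartiles come from the non-missing entries only; missing entries
    are never flagged.  A constant vector has IQR 0 and no exceedances.
    """
    values = np.asarray(values, dtype=float)
    obs = values[~np.isnan(values)]
    if obs.size == 0:
        raise ValueError("all-missing vector has no quartiles")
    if obs.size < 4:
        raise ValueError("need at least 4 non-missing values for IQR fences")
    q1, q3 = np.percentile(obs, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    with np.errstate(invalid="ignore"):
        mask = (values < lo) | (values > hi)
    mask[np.isnan(values)] = False
    return mask


def _callrate_features(vals: np.ndarray) -> np.ndarray:
    return 1.0 - np.isnan(vals).mean(axis=0)


def _callrate_samples(vals: np.ndarray) -> np.ndarray:
    return 1.0 - np.isnan(vals).mean(axis=1)


class _Flow:
    """Mutable QC state: matrix plus telescoping report."""

    def __init__(self, tm: TraitMatrix):
        self.samples = list(tm.samples)
        self.features = tm.features.copy()
        self.values = tm.values.copy()
        self.report = QcReport()

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.samples), len(self.features))

    def step(self, name: str, drop_features: Sequence[str] = (),
             drop_samples: Sequence[str] = (), masked: int = 0,
             reason: str = "") -> None:
        before = self.shape
        if len(drop_features) > 0:
            keep = ~self.features["id"].isin(set(drop_features)).to_numpy()
            self.features = self.features[keep].reset_index(drop=True)
            self.values = self.values[:, keep]
        if len(drop_samples) > 0:
            drop = set(drop_samples)
            keep_idx = [i for i, s in enumerate(self.samples) if s not in drop]
            self.samples = [self.samples[i] for i in keep_idx]
            self.values = self.values[keep_idx]
        self.report.steps.append(QcStep(
            name=name, removed_features=list(drop_features),
            removed_samples=list(drop_samples), masked_cells=masked,
            shape_before=before, shape_after=self.shape, reason=reason))
        if 0 in self.shape:
            raise RuntimeError(f"matrix empty after QC step {name!r}")

    def finish(self) -> tuple[TraitMatrix, QcReport]:
        tm = TraitMatrix(samples=self.samples, features=self.features,
                         values=self.values)
        return tm, self.report


def _mask_iqr_column(col: np.ndarray, k: float,
                     refill_min: bool = False) -> int:
    """Mask IQR outliers in place, iterated to a fixed point.

    Fences are recomputed after each masking round until no new value
    is flagged, so reapplying the step to its own output is a no-op.
    With ``refill_min`` the masked cells are refilled with the
    surviving feature minimum (the metabolomics imputation rule);
    otherwise they stay missing.
    """
    masked_total = 0
    for _ in range(100):
        if np.sum(~np.isnan(col)) < 4:
            break
        m = iqr_outlier_mask(col, k)
        if not m.any():
            break
        masked_total += int(m.sum())
        col[m] = np.nan
        if refill_min:
            miss = np.isnan(col)
            if miss.any() and not miss.all():
                col[miss] = np.nanmin(col)
    return masked_total


def _mask_iqr(flow: _Flow, k: float, step_name: str) -> None:
    masked = 0
    for j in range(flow.values.shape[1]):
        masked += _mask_iqr_column(flow.values[:, j], k)
    flow.step(step_name, masked=masked,
              reason=f"IQR fences at k={k}, iterated to a fixed point")


def _back_transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log10":
        return np.power(10.0, values)
    if transform == "log":
        return np.exp(values)
    return values


def qc_proteomics(raw: TraitMatrix, cfg: QcConfig,
                  replicate_labels: Optional[Sequence] = None
                  ) -> tuple[TraitMatrix, QcReport]:
    """Seven-step aptamer-level proteomics QC.

    Feature metadata may carry boolean columns ``nonhuman`` and
    ``has_target``; analytes flagged non-human or without a protein
    target are removed at the final step regardless of call rate.
    ``replicate_labels`` (one label per sample) enable the replicate-CV
    filter of step 1; without them step 1 is a recorded no-op.
    """
    flow = _Flow(raw)

    # step 1: platform filters (LOD / scale factor / CV) — replicate CV hook
    drop1: list[str] = []
    if replicate_labels is not None:
        labels = np.asarray(replicate_labels)
        raw_scale = _back_transform(flow.values, cfg.transform)
        for j, fid in enumerate(flow.features["id"]):
            cvs = []
            for lab in np.unique(labels):
                grp = raw_scale[labels == lab, j]
                grp = grp[~np.isnan(grp)]
                if grp.size >= 2 and grp.mean() != 0:
                    cvs.append(np.std(grp, ddof=1) / abs(grp.mean()))
            if cvs and np.median(cvs) > cfg.cv_max:
                drop1.append(fid)
    flow.step("platform_filters", drop_features=drop1,
              reason=f"replicate CV > {cfg.cv_max}" if drop1 else "no platform metadata")

    # step 2: IQR-based outlier masking
    _mask_iqr(flow, cfg.iqr_k, "iqr_outliers")

    # step 3: analytes and samples below stage-1 call rate
    cr_f = _callrate_features(flow.values)
    bad_f = [fid for fid, c in zip(flow.features["id"], cr_f)
             if c < cfg.analyte_callrate_stage1]
    flow.step("analyte_callrate_65", drop_features=bad_f,
              reason=f"analyte call rate < {cfg.analyte_callrate_stage1}")
    cr_s = _callrate_samples(flow.values)
    bad_s = [sid for sid, c in zip(flow.samples, cr_s)
             if c < cfg.sample_callrate_stage1]
    flow.step("sample_callrate_65", drop_samples=bad_s,
              reason=f"sample call rate < {cfg.sample_callrate_stage1}")

    # step 4: recomputed analyte call rate, stage 2
    cr_f = _callrate_features(flow.values)
    bad_f = [fid for fid, c in zip(flow.features["id"], cr_f)
             if c < cfg.analyte_callrate_stage2]
    flow.step("analyte_callrate_85", drop_features=bad_f,
              reason=f"analyte call rate < {cfg.analyte_callrate_stage2}")

    # step 5: recomputed sample call rate, stage 2
    cr_s = _callrate_samples(flow.values)
    bad_s = [sid for sid, c in zip(flow.samples, cr_s)
             if c < cfg.sample_callrate_stage2]
    flow.step("sample_callrate_85", drop_samples=bad_s,
              reason=f"sample call rate < {cfg.sample_callrate_stage2}")

    # step 6: back transformation onto the raw scale
    flow.values = _back_transform(flow.values, cfg.transform)
    flow.step("back_transform", reason=f"inverse of {cfg.transform}")

    # step 7: non-human analytes and analytes without protein targets
    drop7: list[str] = []
    cols = flow.features.columns
    nonhuman = flow.features["nonhuman"].fillna(False) if "nonhuman" in cols \
        else pd.Series(False, index=flow.features.index)
    has_target = flow.features["has_target"].fillna(True) if "has_target" in cols \
        else pd.Series(True, index=flow.features.index)
    drop7 = flow.features["id"][nonhuman.astype(bool) | ~has_target.astype(bool)].tolist()
    flow.step("target_annotation", drop_features=drop7,
              reason="non-human or no protein target")

    return flow.finish()


def qc_metabolomics(raw: TraitMatrix, cfg: QcConfig,
                    batch_labels: Sequence,
                    volume_factors: Optional[Sequence[float]] = None
                    ) -> tuple[TraitMatrix, QcReport]:
    """Eleven-step metabolomics QC.

    Minimum-value imputation fills missing entries of *non-xenobiotic*
    metabolites only; xenobiotics are expected to be genuinely absent in
    many samples and stay missing.  Requires an ``xenobiotic`` flag in
    the feature metadata and one batch label per sample.
    """
    if "xenobiotic" not in raw.features.columns or raw.features["xenobiotic"].isna().any():
        raise ValueError("metabolomics QC requires an xenobiotic flag per feature")
    batch = np.asarray(batch_labels)
    if len(batch) != raw.n_samples:
        raise ValueError("need one batch label per sample")
    flow = _Flow(raw)
    batch_by_sample = dict(zip(raw.samples, batch))

    # step 1: volume normalization
    if volume_factors is not None:
        v = np.asarray(volume_factors, dtype=float)
        if len(v) != len(flow.samples) or (v <= 0).any():
            raise ValueError("volume factors must be positive, one per sample")
        flow.values = flow.values / v[:, None]
    flow.step("volume_normalization",
              reason="per-sample volume factors" if volume_factors is not None
              else "no volume factors supplied")

    # step 2: sample missingness
    cr_s = _callrate_samples(flow.values)
    bad_s = [sid for sid, c in zip(flow.samples, cr_s)
             if c < cfg.sample_callrate_stage1]
    flow.step("sample_missingness", drop_samples=bad_s,
              reason=f"sample call rate < {cfg.sample_callrate_stage1}")

    # step 3: metabolite missingness
    cr_f = _callrate_features(flow.values)
    bad_f = [fid for fid, c in zip(flow.features["id"], cr_f)
             if c < cfg.analyte_callrate_stage1]
    flow.step("metabolite_missingness", drop_features=bad_f,
              reason=f"metabolite call rate < {cfg.analyte_callrate_stage1}")

    # step 4: batch-missingness association (Fisher exact, each batch vs rest)
    drop4: list[str] = []
    cur_batch = np.array([batch_by_sample[s] for s in flow.samples])
    ubatch = np.unique(cur_batch)
    if len(ubatch) >= 2:
        for j, fid in enumerate(flow.features["id"]):
            miss = np.isnan(flow.values[:, j])
            if not miss.any() or miss.all():
                continue
            pmin = 1.0
            for b in ubatch:
                inb = cur_batch == b
                tab = [[int((miss & inb).sum()), int((miss & ~inb).sum())],
                       [int((~miss & inb).sum()), int((~miss & ~inb).sum())]]
                pmin = min(pmin, stats.fisher_exact(tab)[1])
            if pmin < cfg.fisher_p:
                drop4.append(fid)
    flow.step("batch_missingness_fisher", drop_features=drop4,
              reason=f"missingness-batch Fisher p < {cfg.fisher_p}")

    # step 5: minimum-value imputation (non-xenobiotic only)
    imputed = 0
    xeno = flow.features["xenobiotic"].astype(bool).to_numpy()
    for j in range(flow.values.shape[1]):
        if xeno[j]:
            continue
        col = flow.values[:, j]
        miss = np.isnan(col)
        if miss.any() and not miss.all():
            col[miss] = np.nanmin(col)
            imputed += int(miss.sum())
    flow.step("minimum_value_imputation", masked=imputed,
              reason="missing -> feature minimum for non-xenobiotics")

    # step 6: non-informative metabolites (constant among observed values)
    drop6 = []
    for j, fid in enumerate(flow.features["id"]):
        obs = flow.values[:, j]
        obs = obs[~np.isnan(obs)]
        if obs.size == 0 or np.nanmax(obs) == np.nanmin(obs):
            drop6.append(fid)
    flow.step("non_informative", drop_features=drop6, reason="constant feature")

    # step 7: IQR-based outlier masking (fixed point); the minimum-value
    # imputation rule is maintained so the non-xenobiotic block stays
    # complete: masked cells refill with the surviving feature minimum
    masked7 = 0
    xeno = flow.features["xenobiotic"].astype(bool).to_numpy()
    for j in range(flow.values.shape[1]):
        masked7 += _mask_iqr_column(flow.values[:, j], cfg.iqr_k,
                                    refill_min=not xeno[j])
    flow.step("iqr_outliers", masked=masked7,
              reason=f"IQR fences at k={cfg.iqr_k}, iterated to a fixed "
                     "point; non-xenobiotic masks refilled with the minimum")

    # step 8: minimum data points
    n_obs = (~np.isnan(flow.values)).sum(axis=0)
    drop8 = [fid for fid, n in zip(flow.features["id"], n_obs)
             if n < cfg.min_datapoints]
    flow.step("min_datapoints", drop_features=drop8,
              reason=f"< {cfg.min_datapoints} data points")

    # step 9: PCA sample outliers on PC1/PC2 at mean +/- k SD, iterated
    # until no sample exceeds the fence (so a second pass is a no-op)
    drop9: list[str] = []
    cur_samples = list(flow.samples)
    cur_vals = flow.values
    for _ in range(50):
        X = cur_vals.copy()
        col_mean = np.nanmean(X, axis=0)
        inds = np.where(np.isnan(X))
        X[inds] = np.take(col_mean, inds[1])
        Xc = X - X.mean(axis=0)
        keep_cols = Xc.std(axis=0) > 0
        if keep_cols.sum() < 2 or len(cur_samples) <= 3:
            break
        U, S, _ = np.linalg.svd(Xc[:, keep_cols], full_matrices=False)
        pcs = U[:, :2] * S[:2]
        mu, sd = pcs.mean(axis=0), pcs.std(axis=0)
        sd[sd == 0] = 1.0
        out = (np.abs(pcs - mu) > cfg.pca_k * sd).any(axis=1)
        if not out.any():
            break
        drop9.extend(s for s, o in zip(cur_samples, out) if o)
        cur_samples = [s for s, o in zip(cur_samples, out) if not o]
        cur_vals = cur_vals[~out]
    flow.step("pca_sample_outliers", drop_samples=drop9,
              reason=f"|PC1/PC2| beyond mean +/- {cfg.pca_k} SD, iterated")

    # step 10: batch-median alignment
    if cfg.align_batches:
        cur_batch = np.array([batch_by_sample[s] for s in flow.samples])
        for j in range(flow.values.shape[1]):
            col = flow.values[:, j]
            overall = np.nanmedian(col)
            for b in np.unique(cur_batch):
                sel = cur_batch == b
                med = np.nanmedian(col[sel])
                if np.isfinite(med):
                    col[sel] += overall - med
    flow.step("batch_alignment",
              reason="per-batch medians aligned to the overall median"
              if cfg.align_batches else "disabled")

    # step 11: final matrix and back transformation
    flow.values = _back_transform(flow.values, cfg.transform)
    flow.step("back_transform", reason=f"inverse of {cfg.transform}")

    return flow.finish()
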