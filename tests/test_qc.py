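"""Proteomics and metabolomics QC: filters, imputation, reporting."""

import numpy as np
import pandas as pd
import pytest

from ancestryqtl.containers import TraitMatrix
from ancestryqtl.qc import QcConfig, iqr_outlier_mask, qc_metabolomics, qc_proteomics

from conftest import metabolite_matrix


def protein_matrix(values: np.ndarray, nonhuman=None, has_target=None) -> TraitMatrix:
    n, m = values.shape
    feats = pd.DataFrame({
        "id": [f"apt{j}" for j in range(m)],
        "kind": "protein", "chrom": "chr1",
        "gene_start": [1000 * (j + 1) for j in range(m)],
        "super_pathway": None, "xenobiotic": False,
    })
    if nonhuman is not None:
        feats["nonhuman"] = nonhuman
    if has_target is not None:
        feats["has_target"] = has_target
    return TraitMatrix(samples=[f"s{i}" for i in range(n)], features=feats,
                       values=values)


class TestIqrMask:
    def test_single_outlier_flagged(self):
        # quartile oracle by enumeration: Q1=2, Q3=4, fences [-1, 7]
        mask = iqr_outlier_mask(np.array([1, 2, 3, 4, 100.0]), k=1.5)
        assert mask.tolist() == [False, False, False, False, True]

    def test_constant_vector_all_false(self):
        assert not iqr_outlier_mask(np.full(10, 3.0), k=1.5).any()

    def test_negation_symmetry(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        x[:3] = [8, -9, 7.5]
        assert np.array_equal(iqr_outlier_mask(x), iqr_outlier_mask(-x))

    def test_missing_never_flagged_and_all_missing_rejected(self):
        x = np.array([1.0, np.nan, 2, 3, 4])
        assert not iqr_outlier_mask(x)[1]
        with pytest.raises(ValueError):
            iqr_outlier_mask(np.full(5, np.nan))


class TestProteomicsQc:
    def test_low_callrate_analyte_removed_at_stage1(self):
        # one analyte 50%-observed against a 0.65 stage-1 cutoff
        vals = np.ones((6, 4)) + np.arange(24).reshape(6, 4) * 0.01
        vals[:3, 2] = np.nan
        tm = protein_matrix(vals)
        clean, report = qc_proteomics(tm, QcConfig())
        step = next(s for s in report.steps if s.name == "analyte_callrate_65")
        assert step.removed_features == ["apt2"]
        assert "apt2" not in clean.feature_ids

    def test_clean_matrix_is_identity(self):
        # uniform data has no 1.5*IQR exceedances, so nothing is touched
        rng = np.random.default_rng(2)
        vals = rng.uniform(9, 11, size=(40, 5))
        tm = protein_matrix(vals)
        clean, report = qc_proteomics(tm, QcConfig())
        assert np.array_equal(clean.values, vals)
        assert all(not s.removed_features and not s.removed_samples
                   for s in report.steps)

    def test_nonhuman_flag_removed_regardless_of_callrate(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(10, 0.5, size=(30, 3))
        tm = protein_matrix(vals, nonhuman=[False, True, False])
        clean, report = qc_proteomics(tm, QcConfig())
        assert "apt1" not in clean.feature_ids
        step = next(s for s in report.steps if s.name == "target_annotation")
        assert step.removed_features == ["apt1"]

    def test_report_telescopes(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(10, 1, size=(50, 8))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        vals[:, 0] = np.where(np.arange(50) < 30, np.nan, vals[:, 0])
        clean, report = qc_proteomics(protein_matrix(vals), QcConfig())
        assert report.telescopes()
        assert report.final_shape == (clean.n_samples, clean.n_features)

    def test_back_transform_inverts_log10(self):
        vals = np.log10(np.full((30, 2), 250.0))
        clean, _ = qc_proteomics(protein_matrix(vals),
                                 QcConfig(transform="log10"))
        assert np.allclose(clean.values, 250.0)

    def test_no_value_invention(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(10, 1, size=(60, 6))
        vals[rng.random(vals.shape) < 0.1] = np.nan
        clean, _ = qc_proteomics(protein_matrix(vals), QcConfig())
        inputs = set(np.round(vals[np.isfinite(vals)], 12))
        outputs = clean.values[np.isfinite(clean.values)]
        assert all(np.round(v, 12) in inputs for v in outputs)


class TestMetabolomicsQc:
    def test_minimum_value_imputation_non_xenobiotic_only(self):
        tm, batches = metabolite_matrix(n_samples=80, n_features=4, seed=6,
                                        missing_rate=0.0, n_xeno=1)
        tm.values[2, 1] = np.nan   # non-xenobiotic, gets feature minimum
        tm.values[3, 0] = np.nan   # xenobiotic, stays missing
        expected_min = np.nanmin(tm.values[:, 1])
        clean, report = qc_metabolomics(tm, QcConfig(min_datapoints=10,
                                                     align_batches=False),
                                        batches)
        assert clean.values[2, 1] == expected_min
        assert np.isnan(clean.values[3, 0])

    def test_sparse_metabolite_removed_at_min_datapoints(self):
        # call rate 49/60 = 0.82 passes the 0.65 gate but misses the
        # 50-data-point floor
        tm, batches = metabolite_matrix(n_samples=60, n_features=5, seed=7,
                                        missing_rate=0.0, n_xeno=1)
        tm.values[49:, 0] = np.nan
        clean, report = qc_metabolomics(tm, QcConfig(min_datapoints=50),
                                        batches)
        step = next(s for s in report.steps if s.name == "min_datapoints")
        assert "met0" in step.removed_features
        assert "met0" not in clean.feature_ids

    def test_missing_xenobiotic_flag_rejected(self):
        tm, batches = metabolite_matrix(seed=8)
        tm.features.loc[0, "xenobiotic"] = None
        with pytest.raises(ValueError, match="xenobiotic"):
            qc_metabolomics(tm, QcConfig(), batches)

    def test_idempotence(self):
        # reapplication equivalence on a stable log-scale matrix; the
        # batch-alignment step is excluded because shifting batches can
        # re-expose borderline cells to the IQR fences on a second pass
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, size=(150, 40))
        vals[rng.random(vals.shape) < 0.05] = np.nan
        feats = pd.DataFrame({
            "id": [f"met{j}" for j in range(40)], "kind": "metabolite",
            "chrom": None, "gene_start": None, "super_pathway": "Lipid",
            "xenobiotic": [j < 5 for j in range(40)]})
        batches = rng.integers(0, 2, size=150)
        tm = TraitMatrix(samples=[f"s{i}" for i in range(150)],
                         features=feats, values=vals)
        cfg = QcConfig(min_datapoints=20, align_batches=False)
        clean1, _ = qc_metabolomics(tm, cfg, batches)
        keep = [tm.samples.index(s) for s in clean1.samples]
        clean2, _ = qc_metabolomics(clean1, cfg, batches[keep])
        assert clean2.samples == clean1.samples
        assert clean2.feature_ids == clean1.feature_ids
        np.testing.assert_allclose(np.nan_to_num(clean2.values, nan=-1e18),
                                   np.nan_to_num(clean1.values, nan=-1e18),
                                   rtol=0, atol=1e-12)

    def test_proteomics_idempotence(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(10, 1, size=(100, 60))
        vals[rng.random(vals.shape) < 0.05] = np.nan
        cfg = QcConfig()
        clean1, _ = qc_proteomics(protein_matrix(vals), cfg)
        clean2, _ = qc_proteomics(clean1, cfg)
        assert clean2.feature_ids == clean1.feature_ids
        assert clean2.samples == clean1.samples
        np.testing.assert_allclose(np.nan_to_num(clean2.values, nan=-1e18),
                                   np.nan_to_num(clean1.values, nan=-1e18),
                                   rtol=0, atol=1e-12)

    def test_batch_alignment_equalizes_medians(self):
        tm, batches = metabolite_matrix(n_samples=160, n_features=4, seed=11,
                                        missing_rate=0.0, n_xeno=0)
        tm.values[batches == 1] += 2.0   # strong batch shift
        clean, _ = qc_metabolomics(tm, QcConfig(min_datapoints=10), batches)
        keep = [tm.samples.index(s) for s in clean.samples]
        b = batches[keep]
        for j in range(clean.n_features):
            med0 = np.nanmedian(clean.values[b == 0, j])
            med1 = np.nanmedian(clean.values[b == 1, j])
            assert abs(med0 - med1) < 0.15

    def test_empty_after_step_is_explicit_failure(self):
        tm, batches = metabolite_matrix(n_samples=30, n_features=3, seed=12,
                                        missing_rate=0.0, n_xeno=0)
        with pytest.raises(RuntimeError, match="min_datapoints"):
            qc_metabolomics(tm, QcConfig(min_datapoints=10_000), batches)
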