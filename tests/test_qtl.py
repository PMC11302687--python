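"""Additive-model scan, thresholds, cis/trans, inflation and LD blocks."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ancestryqtl.containers import LDBlock, TraitMatrix
from ancestryqtl.qtl import (annotate_cis_trans, assign_ld_blocks_and_hotspots,
                             classify_cis_trans, count_independent_components,
                             derive_study_threshold, filter_inflated_features,
                             fit_additive_scan, round_sig, select_sentinels)
from ancestryqtl.simulate import VariantSpec, simulate_genotypes


def trait_matrix_from(values, geno, gene_start=10_000):
    n, m = values.shape
    feats = pd.DataFrame({
        "id": [f"f{j}" for j in range(m)], "kind": "protein",
        "chrom": "chr1", "gene_start": gene_start,
        "super_pathway": None, "xenobiotic": False})
    return TraitMatrix(samples=list(geno.samples), features=feats,
                       values=values)


@pytest.fixture(scope="module")
def scan_setup():
    specs = [VariantSpec(maf_afr=0.3, maf_eur=0.25) for _ in range(6)]
    _, geno = simulate_genotypes(30, 200, specs, seed=80)
    rng = np.random.default_rng(81)
    cov = pd.DataFrame({"sample": geno.samples,
                        "age": rng.normal(70, 8, 200),
                        "sex": rng.integers(0, 2, 200).astype(float)})
    vals = rng.normal(0, 1, size=(200, 3))
    vals[:, 0] += 0.4 * geno.dosages[:, 2]
    traits = trait_matrix_from(vals, geno)
    return geno, traits, cov


class TestScan:
    def test_noise_free_trait_recovers_beta_exactly(self):
        specs = [VariantSpec(maf_afr=0.3, maf_eur=0.3)]
        _, geno = simulate_genotypes(30, 100, specs, seed=82)
        vals = (0.5 * geno.dosages[:, [0]])
        traits = trait_matrix_from(vals, geno)
        res = fit_additive_scan(geno, traits, None, transform="none")
        row = res.table.iloc[0]
        assert np.isclose(row["beta"], 0.5, atol=1e-12)
        assert row["p"] < 1e-100

    def test_matches_ols_oracle(self, scan_setup):
        geno, traits, cov = scan_setup
        res = fit_additive_scan(geno, traits, cov, transform="none")
        for _, row in res.table.iterrows():
            j = traits.feature_ids.index(row["feature"])
            g = geno.dosage_of(row["variant"])
            X = sm.add_constant(np.column_stack([
                g, cov["age"].to_numpy(), cov["sex"].to_numpy()]))
            fit = sm.OLS(traits.values[:, j], X).fit()
            assert np.isclose(row["beta"], fit.params[1], rtol=1e-8)
            assert np.isclose(row["se"], fit.bse[1], rtol=1e-8)
            assert np.isclose(row["p"], fit.pvalues[1], rtol=1e-6)

    def test_null_type_one_error(self):
        # 1000 independent null pairs: fraction p < 0.05 inside the
        # binomial 99% band around 0.05
        specs = [VariantSpec(maf_afr=0.3, maf_eur=0.3) for _ in range(20)]
        _, geno = simulate_genotypes(30, 300, specs, seed=83)
        rng = np.random.default_rng(84)
        vals = rng.normal(size=(300, 50))
        traits = trait_matrix_from(vals, geno)
        res = fit_additive_scan(geno, traits, None, transform="none")
        frac = (res.table["p"] < 0.05).mean()
        assert 0.035 <= frac <= 0.065

    def test_z_equals_beta_over_se(self, scan_setup):
        geno, traits, cov = scan_setup
        res = fit_additive_scan(geno, traits, cov, transform="none")
        assert np.allclose(res.table["z"],
                           res.table["beta"] / res.table["se"], rtol=1e-9)

    def test_sparse_feature_skipped(self, scan_setup):
        geno, traits, _ = scan_setup
        vals = traits.values.copy()
        vals[20:, 1] = np.nan   # 20 observations < 30 floor
        sparse = trait_matrix_from(vals, geno)
        res = fit_additive_scan(geno, sparse, None, transform="none")
        assert "f1" in res.skipped["feature"].tolist()
        assert "f1" not in res.table["feature"].tolist()

    def test_rank_deficient_covariates_flagged(self, scan_setup):
        geno, traits, cov = scan_setup
        bad = cov.copy()
        bad["age2"] = bad["age"] * 2.0   # collinear
        res = fit_additive_scan(geno, traits, bad, transform="none")
        assert len(res.flagged) == traits.n_features
        assert res.table.empty

    def test_transforms(self, scan_setup):
        geno, traits, _ = scan_setup
        pos_vals = np.exp(traits.values)
        pos = trait_matrix_from(pos_vals, geno)
        for tr in ("log10+zscale", "median-log10"):
            res = fit_additive_scan(geno, pos, None, transform=tr)
            assert len(res.table) == geno.n_variants * pos.n_features
        with pytest.raises(ValueError):
            fit_additive_scan(geno, traits, None, transform="log10+zscale")


class TestComponents:
    def test_rank_one_matrix(self):
        u = np.outer(np.arange(20.0), np.ones(5))
        assert count_independent_components(u, 0.95) == 1

    def test_var_frac_one_is_rank(self):
        rng = np.random.default_rng(85)
        X = rng.normal(size=(30, 4)) @ rng.normal(size=(4, 10))
        assert count_independent_components(X, 1.0) == 4

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(86)
        X = rng.normal(size=(100, 10))
        Xc = X - X.mean(axis=0)
        ev = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        frac = np.cumsum(ev) / ev.sum()
        oracle = int(np.argmax(frac >= 0.95)) + 1
        assert count_independent_components(X, 0.95) == oracle

    def test_rejects_non_finite(self):
        X = np.ones((10, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            count_independent_components(X)


class TestThreshold:
    @pytest.mark.parametrize("ncomp, expected", [
        (1472, 3.40e-11), (336, 1.49e-10), (766, 6.53e-11), (281, 1.78e-10)])
    def test_study_wide_arithmetic(self, ncomp, expected):
        thr = derive_study_threshold(ncomp)
        assert round_sig(thr.study_wide, 3) == pytest.approx(expected, rel=1e-12)

    def test_identity_and_validation(self):
        assert derive_study_threshold(1).study_wide == 5e-8
        with pytest.raises(ValueError):
            derive_study_threshold(0)


class TestCisTrans:
    @pytest.mark.parametrize("vpos, gchrom, expected", [
        (5_000_000, "chr1", "cis"),              # at the gene start
        (6_000_000, "chr1", "cis"),              # exactly 1 Mb: inclusive
        (6_000_001, "chr1", "trans"),            # one bp beyond
        (5_000_000, "chr2", "trans"),            # other chromosome
    ])
    def test_window_rule(self, vpos, gchrom, expected):
        assert classify_cis_trans("chr1", vpos, gchrom, 5_000_000) == expected

    def test_metabolite_rejected(self):
        tab = pd.DataFrame([dict(feature="m1", variant="chr1:10:A:C",
                                 chrom="chr1", pos=10)])
        feats = pd.DataFrame([dict(id="m1", kind="metabolite", chrom=None,
                                   gene_start=None)])
        with pytest.raises(ValueError, match="protein"):
            annotate_cis_trans(tab, feats)


def _qtl_rows(feature, chroms, maf=0.3, callrate=1.0, sig=True):
    return pd.DataFrame([dict(feature=feature, variant=f"{c}:100:A:C",
                              chrom=c, pos=100, beta=0.5, se=0.05, z=10.0,
                              p=1e-12, n=100, maf=maf, callrate=callrate,
                              sig=sig) for c in chroms])


class TestInflationFilter:
    def test_rescue_prunes_low_quality_hits(self):
        # 6 chromosomes against a limit of 5, all surplus at MAF 0.02
        good = _qtl_rows("fA", [f"chr{i}" for i in range(1, 6)])
        bad = _qtl_rows("fA", ["chr6"], maf=0.02)
        kept, removed, actions = filter_inflated_features(
            pd.concat([good, bad], ignore_index=True), chrom_limit=5)
        assert removed == []
        assert len(kept) == 5
        assert "chr6" not in kept["chrom"].tolist()

    def test_feature_removed_when_rescue_fails(self):
        rows = _qtl_rows("fB", [f"chr{i}" for i in range(1, 9)])
        kept, removed, _ = filter_inflated_features(rows, chrom_limit=5)
        assert removed == ["fB"]
        assert kept.empty

    def test_modest_feature_untouched(self):
        rows = _qtl_rows("fC", ["chr1", "chr2"])
        kept, removed, _ = filter_inflated_features(rows, chrom_limit=5)
        assert removed == []
        pd.testing.assert_frame_equal(kept, rows)


class TestBlocks:
    BLOCKS = [LDBlock("chr1", 100, 200, 0), LDBlock("chr1", 200, 300, 1),
              LDBlock("chr2", 1, 1000, 2)]

    def _records(self, positions, chrom="chr1"):
        return pd.DataFrame([dict(feature=f"f{i}", variant=f"{chrom}:{p}:A:C",
                                  chrom=chrom, pos=p, sig=True)
                             for i, p in enumerate(positions)])

    def test_boundary_belongs_to_starting_block(self):
        out, _ = assign_ld_blocks_and_hotspots(self._records([200]), self.BLOCKS)
        assert out["ld_block"].tolist() == [1]   # half-open: 200 starts block 1

    def test_outside_all_blocks_is_unblocked(self):
        out, counts = assign_ld_blocks_and_hotspots(self._records([5000]),
                                                    self.BLOCKS)
        assert out["ld_block"].tolist() == [-1]
        assert counts.set_index("ld_block").loc[-1, "n_features"] == 1

    def test_hotspot_count(self):
        recs = self._records([150, 160, 170])
        _, counts = assign_ld_blocks_and_hotspots(recs, self.BLOCKS)
        assert counts.set_index("ld_block").loc[0, "n_features"] == 3

    def test_matches_interval_scan_oracle(self):
        rng = np.random.default_rng(87)
        pos = rng.integers(1, 1200, size=200)
        recs = self._records(pos)
        out, _ = assign_ld_blocks_and_hotspots(recs, self.BLOCKS)
        for _, row in out.iterrows():
            match = [b.index for b in self.BLOCKS
                     if b.contains(row["chrom"], row["pos"])]
            expected = match[0] if match else -1
            assert row["ld_block"] == expected

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            assign_ld_blocks_and_hotspots(
                self._records([150]),
                [LDBlock("chr1", 100, 250, 0), LDBlock("chr1", 200, 300, 1)])


def test_sentinel_tie_breaking():
    rows = pd.DataFrame([
        dict(feature="f", variant="chr1:300:A:C", chrom="chr1", pos=300,
             z=5.0, p=1e-8, ld_block=0),
        dict(feature="f", variant="chr1:100:A:C", chrom="chr1", pos=100,
             z=-6.0, p=1e-8, ld_block=0),     # same p, larger |z| wins
        dict(feature="f", variant="chr1:200:A:C", chrom="chr1", pos=200,
             z=4.0, p=1e-9, ld_block=1),
    ])
    sent = select_sentinels(rows)
    chosen = sent.set_index("ld_block")["variant"]
    assert chosen.loc[0] == "chr1:100:A:C"
    assert chosen.loc[1] == "chr1:200:A:C"
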