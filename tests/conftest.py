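"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ancestryqtl.containers import EffectSpec, TraitMatrix
from ancestryqtl.pipeline import PipelineConfig, run_pipeline
from ancestryqtl.simulate import (CovariateSpec, VariantSpec,
                                  simulate_genotypes, simulate_omics)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-ancestry cohort: 3 LD blocks x 4 variants, 2 planted features.

    feat_shared has equal effects in both ancestries; feat_eur_only has
    a EUR-only effect.  n = 400 per ancestry, moderate LD (r = 0.5).
    """
    specs = [VariantSpec(maf_afr=0.3, maf_eur=0.25, ld_block=b, chrom="chr1",
                         pos=10_000 + (b * 4 + k) * 50_000)
             for b in range(3) for k in range(4)]
    geno_afr, geno_eur = simulate_genotypes(400, 400, specs,
                                            within_block_r=0.5, seed=11)
    v0 = geno_eur.variants[1].id
    v1 = geno_eur.variants[5].id
    effects = [
        EffectSpec(feature="feat_shared", variant=v0, beta_afr=0.5,
                   beta_eur=0.5, cis=True),
        EffectSpec(feature="feat_eur_only", variant=v1, beta_afr=0.0,
                   beta_eur=0.5, cis=True),
    ]
    traits_afr, traits_eur, cov_afr, cov_eur = simulate_omics(
        geno_afr, geno_eur, effects,
        covariate_spec=CovariateSpec(age_beta=0.02, sex_beta=0.1),
        noise_sd=1.0, seed=12)
    return dict(geno_afr=geno_afr, geno_eur=geno_eur,
                traits_afr=traits_afr, traits_eur=traits_eur,
                cov_afr=cov_afr, cov_eur=cov_eur, effects=effects)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full pipeline execution on the bundled synthetic study."""
    out = tmp_path_factory.mktemp("demo_pipeline")
    cfg = PipelineConfig(seed=1, out_dir=str(out))
    return run_pipeline(cfg)


def metabolite_matrix(n_samples: int = 120, n_features: int = 6,
                      seed: int = 0, missing_rate: float = 0.1,
                      n_xeno: int = 2) -> tuple[TraitMatrix, np.ndarray]:
    """Hand-rolled metabolomics-like matrix with xenobiotic flags."""
    rng = np.random.default_rng(seed)
    vals = rng.lognormal(0.0, 0.5, size=(n_samples, n_features))
    mask = rng.random(vals.shape) < missing_rate
    vals[mask] = np.nan
    feats = pd.DataFrame({
        "id": [f"met{j}" for j in range(n_features)],
        "kind": "metabolite",
        "chrom": None, "gene_start": None,
        "super_pathway": "Lipid",
        "xenobiotic": [j < n_xeno for j in range(n_features)],
    })
    batches = rng.integers(0, 2, size=n_samples)
    samples = [f"s{i}" for i in range(n_samples)]
    return TraitMatrix(samples=samples, features=feats, values=vals), batches
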