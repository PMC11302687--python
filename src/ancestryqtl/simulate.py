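"""Two-ancestry synthetic cohort generator.

Generates the inputs the pipeline consumes — per-ancestry genotype
dosage matrices with divergent allele frequencies and blockwise LD,
protein/metabolite abundance matrices with planted cis/trans effects
(ancestry-shared or ancestry-specific), covariate tables with batch
structure, and a binary-trait GWAS whose loci may or may not share
causal variants with the molecular traits.

The LD model is a Gaussian-copula haplotype scheme: each haplotype is a
latent standard normal vector, exchangeably correlated at ``r`` within
an LD block, thresholded at the allele-frequency quantile.  Dosage is
the sum of two independent haplotypes, so variants in a block have
pairwise dosage correlation close to ``r`` and per-column allele
frequency matches the requested MAF in expectation.  Dosages are hard
0/1/2 calls; imputation uncertainty is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (EffectSpec, GenotypeMatrix, GwasSumstats, LDBlock,
                         TraitMatrix, VariantRecord, make_variant_id)

__all__ = [
    "VariantSpec",
    "CovariateSpec",
    "simulate_genotypes",
    "simulate_omics",
    "simulate_gwas",
    "logistic_score_test",
    "blocks_from_variants",
]

# ref/alt pairs exclude strand-ambiguous A/T and C/G combinations,
# emulating a post-QC imputation panel
_ALLELE_PAIRS = (("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                 ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"))


@dataclass(frozen=True)
class VariantSpec:
    """Requested per-variant simulation parameters.

    ``pos`` may be left None, in which case variants are laid out 5 kb
    apart along ``chrom`` in input order.
    """

    maf_afr: float
    maf_eur: float
    ld_block: Optional[int] = None
    chrom: str = "chr1"
    pos: Optional[int] = None


@dataclass(frozen=True)
class CovariateSpec:
    """Effect sizes of the simulated covariates on every trait.

    A reduced stand-in for the age / sex / array-batch covariate set of
    a real cohort: age is drawn N(70, 8), sex Bernoulli(0.5), batch one
    of ``n_batches`` labels.
    """

    age_beta: float = 0.0
    sex_beta: float = 0.0
    batch_beta: float = 0.0
    n_batches: int = 2


def _validate_specs(variant_spec: Sequence[VariantSpec], within_block_r: float) -> None:
    if not 0.0 <= within_block_r < 1.0:
        raise ValueError(f"within_block_r={within_block_r} outside [0, 1)")
    for i, vs in enumerate(variant_spec):
        for name, maf in (("maf_afr", vs.maf_afr), ("maf_eur", vs.maf_eur)):
            if not 0.0 < maf <= 0.5:
                raise ValueError(f"variant {i}: {name}={maf} outside (0, 0.5]")


def _layout_variants(variant_spec: Sequence[VariantSpec],
                     rng: np.random.Generator) -> list[VariantRecord]:
    records = []
    next_pos: dict[str, int] = {}
    for vs in variant_spec:
        if vs.pos is not None:
            pos = int(vs.pos)
        else:
            pos = next_pos.get(vs.chrom, 10_000)
        next_pos[vs.chrom] = pos + 5_000
        ref, alt = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
        vid = make_variant_id(vs.chrom, pos, ref, alt)
        records.append(VariantRecord(id=vid, chrom=vs.chrom, pos=pos,
                                     maf_afr=vs.maf_afr, maf_eur=vs.maf_eur,
                                     ld_block=vs.ld_block))
    return records


def _latent_r_for_dosage_r(target_r: float, maf: float) -> float:
    """Latent-normal correlation whose thresholded indicators correlate at
    ``target_r``.

    Thresholding attenuates correlation, so the latent value is solved
    from the tetrachoric relation corr = (Phi2(t,t;rho) - p^2)/(p(1-p))
    with t the maf quantile.  Dosages inherit the haplotype-indicator
    correlation exactly (independent sum of two haplotypes).
    """
    if target_r <= 0:
        return 0.0
    t = stats.norm.ppf(maf)
    p = maf

    def binary_corr(rho: float) -> float:
        joint = stats.multivariate_normal(mean=[0.0, 0.0],
                                          cov=[[1.0, rho], [rho, 1.0]]
                                          ).cdf([t, t])
        return (joint - p * p) / (p * (1 - p))

    from scipy.optimize import brentq
    hi = 1.0 - 1e-9
    if binary_corr(hi) <= target_r:
        return hi
    return float(brentq(lambda a: binary_corr(a) - target_r, 0.0, hi,
                        xtol=1e-6))


def _draw_haplotypes(n_hap: int, mafs: np.ndarray, blocks: np.ndarray,
                     r: float, rng: np.random.Generator) -> np.ndarray:
    """Thresholded exchangeable-within-block latent normals -> 0/1 alleles.

    The within-block latent correlation is calibrated (at each block's
    mean MAF) so the resulting *dosage* correlation matches ``r``.
    """
    m = len(mafs)
    eps = rng.standard_normal((n_hap, m))
    z = eps.copy()
    if r > 0:
        for b in np.unique(blocks[blocks >= 0]):
            cols = np.flatnonzero(blocks == b)
            a = _latent_r_for_dosage_r(r, float(mafs[cols].mean()))
            shared = rng.standard_normal((n_hap, 1))
            z[:, cols] = np.sqrt(a) * shared + np.sqrt(1.0 - a) * eps[:, cols]
    thresh = stats.norm.ppf(mafs)
    return (z < thresh).astype(float)


def simulate_genotypes(n_afr: int, n_eur: int,
                       variant_spec: Sequence[VariantSpec],
                       within_block_r: float = 0.0,
                       seed: int = 0) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Draw hard-call dosage matrices for the two ancestries.

    Returns ``(afr, eur)`` genotype matrices over an identical variant
    panel; only allele frequencies differ between ancestries.
    """
    if n_afr < 30 or n_eur < 30:
        raise ValueError("need at least 30 samples per ancestry")
    _validate_specs(variant_spec, within_block_r)

    ss = np.random.SeedSequence(seed)
    rng_layout, rng_afr, rng_eur = (np.random.default_rng(s) for s in ss.spawn(3))
    records = _layout_variants(variant_spec, rng_layout)
    blocks = np.array([-1 if vs.ld_block is None else vs.ld_block
                       for vs in variant_spec])

    out = []
    for ancestry, n, rng in (("AFR", n_afr, rng_afr), ("EUR", n_eur, rng_eur)):
        mafs = np.array([getattr(vs, f"maf_{ancestry.lower()}") for vs in variant_spec])
        hap1 = _draw_haplotypes(n, mafs, blocks, within_block_r, rng)
        hap2 = _draw_haplotypes(n, mafs, blocks, within_block_r, rng)
        dos = hap1 + hap2
        samples = [f"{ancestry}_{i:05d}" for i in range(n)]
        out.append(GenotypeMatrix(samples=samples, variants=list(records),
                                  dosages=dos, ancestry=ancestry))
    return out[0], out[1]


def blocks_from_variants(variants: Sequence[VariantRecord],
                         pad: int = 2_000) -> list[LDBlock]:
    """Half-open LD-block intervals spanning each block's variants."""
    by_block: dict[int, list[VariantRecord]] = {}
    for v in variants:
        if v.ld_block is not None:
            by_block.setdefault(v.ld_block, []).append(v)
    blocks = []
    for idx in sorted(by_block):
        vs = by_block[idx]
        chroms = {v.chrom for v in vs}
        if len(chroms) != 1:
            raise ValueError(f"ld_block {idx} spans chromosomes {chroms}")
        lo = min(v.pos for v in vs)
        hi = max(v.pos for v in vs)
        blocks.append(LDBlock(chrom=chroms.pop(), start=max(1, lo - pad),
                              end=hi + pad + 1, index=idx))
    return blocks


def _default_feature_meta(effects: Sequence[EffectSpec],
                          geno: GenotypeMatrix,
                          kind: str) -> pd.DataFrame:
    """Feature metadata inferred from the planted effects.

    Proteins get a coding-gene start at the causal variant (cis flag
    true) or on a distant locus (cis false); metabolites get a
    super-pathway label and a non-xenobiotic flag.
    """
    rows = []
    seen = set()
    for eff in effects:
        if eff.feature in seen:
            continue
        seen.add(eff.feature)
        v = geno.variants[geno.index_of(eff.variant)]
        if kind == "protein":
            gene_start = v.pos if eff.cis else v.pos + 50_000_000
            rows.append(dict(id=eff.feature, kind="protein", chrom=v.chrom,
                             gene_start=gene_start, super_pathway=None,
                             xenobiotic=False))
        else:
            rows.append(dict(id=eff.feature, kind="metabolite", chrom=None,
                             gene_start=None, super_pathway="Amino Acid",
                             xenobiotic=False))
    return pd.DataFrame(rows)


def _simulate_covariates(samples: list[str], spec: CovariateSpec,
                         rng: np.random.Generator) -> pd.DataFrame:
    n = len(samples)
    return pd.DataFrame({
        "sample": samples,
        "age": rng.normal(70.0, 8.0, size=n),
        "sex": rng.integers(0, 2, size=n).astype(float),
        "batch": rng.integers(0, spec.n_batches, size=n).astype(float),
    })


def _trait_values(geno: GenotypeMatrix, effects: Sequence[EffectSpec],
                  betas_attr: str, feature_ids: list[str],
                  cov: pd.DataFrame, spec: CovariateSpec,
                  noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    n = geno.n_samples
    vals = rng.normal(0.0, noise_sd, size=(n, len(feature_ids)))
    fidx = {f: j for j, f in enumerate(feature_ids)}
    for eff in effects:
        beta = getattr(eff, betas_attr)
        if beta != 0.0:
            vals[:, fidx[eff.feature]] += beta * geno.dosage_of(eff.variant)
    age_c = (cov["age"].to_numpy() - cov["age"].mean())
    cov_term = (spec.age_beta * age_c
                + spec.sex_beta * cov["sex"].to_numpy()
                + spec.batch_beta * cov["batch"].to_numpy())
    return vals + cov_term[:, None]


def _apply_missingness(vals: np.ndarray, meta: pd.DataFrame,
                       cov: pd.DataFrame, missing_rate: float,
                       rng: np.random.Generator) -> np.ndarray:
    out = vals.copy()
    if missing_rate > 0:
        mask = rng.random(out.shape) < missing_rate
        out[mask] = np.nan
    # xenobiotics carry structured block missingness: one whole batch absent
    xeno_cols = np.flatnonzero(meta["xenobiotic"].fillna(False).to_numpy())
    if len(xeno_cols) > 0:
        batches = cov["batch"].to_numpy()
        for j in xeno_cols:
            drop_batch = rng.choice(np.unique(batches))
            out[batches == drop_batch, j] = np.nan
    return out


def simulate_omics(geno_afr: GenotypeMatrix, geno_eur: GenotypeMatrix,
                   effects: Sequence[EffectSpec],
                   covariate_spec: CovariateSpec = CovariateSpec(),
                   noise_sd: float = 1.0,
                   missing_rate: float = 0.0,
                   seed: int = 0,
                   feature_meta: Optional[pd.DataFrame] = None,
                   kind: str = "protein",
                   ) -> tuple[TraitMatrix, TraitMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate trait matrices for both ancestries plus covariate tables.

    trait = sum(beta * dosage) + covariate terms + N(0, noise_sd^2);
    entries are then masked missing completely at random at
    ``missing_rate`` (xenobiotic metabolites additionally lose a whole
    batch, emulating platform panels absent from some runs).
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    panel = set(geno_afr.variant_ids)
    if set(geno_eur.variant_ids) != panel:
        raise ValueError("ancestry genotype panels differ")
    for eff in effects:
        if eff.variant not in panel:
            raise ValueError(f"effect variant {eff.variant!r} not in genotype panel")

    if feature_meta is None:
        feature_meta = _default_feature_meta(effects, geno_afr, kind)
    else:
        known = set(feature_meta["id"])
        for eff in effects:
            if eff.feature not in known:
                raise ValueError(f"effect feature {eff.feature!r} not in feature_meta")
    feature_ids = feature_meta["id"].tolist()

    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(6)
    out = []
    for geno, attr, s_cov, s_val, s_miss in (
            (geno_afr, "beta_afr", seeds[0], seeds[1], seeds[2]),
            (geno_eur, "beta_eur", seeds[3], seeds[4], seeds[5])):
        cov = _simulate_covariates(geno.samples, covariate_spec,
                                   np.random.default_rng(s_cov))
        vals = _trait_values(geno, effects, attr, feature_ids, cov,
                             covariate_spec, noise_sd,
                             np.random.default_rng(s_val))
        vals = _apply_missingness(vals, feature_meta, cov, missing_rate,
                                  np.random.default_rng(s_miss))
        out.append((TraitMatrix(samples=list(geno.samples),
                                features=feature_meta.copy(), values=vals), cov))
    (traits_afr, cov_afr), (traits_eur, cov_eur) = out
    return traits_afr, traits_eur, cov_afr, cov_eur


def logistic_score_test(G: np.ndarray, y: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant logistic score test of case status on dosage.

    beta = U/V and se = V^{-1/2} with U = g'(y - ybar) and
    V = ybar(1-ybar) * sum((g - gbar)^2); the z = beta/se is the score
    statistic, asymptotically equivalent to the Wald z of a per-variant
    logistic regression.  Returns (beta, se, p, ok) with ``ok`` false
    for monomorphic columns.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    ybar = y.mean()
    Gc = G - G.mean(axis=0)
    U = Gc.T @ (y - ybar)
    V = ybar * (1 - ybar) * (Gc ** 2).sum(axis=0)
    ok = V > 0
    beta = np.full(len(V), np.nan)
    se = np.full(len(V), np.nan)
    beta[ok] = U[ok] / V[ok]
    se[ok] = 1.0 / np.sqrt(V[ok])
    z = np.zeros_like(beta)
    z[ok] = beta[ok] / se[ok]
    p = 2.0 * stats.norm.sf(np.abs(z))
    return beta, se, p, ok


def simulate_gwas(geno: GenotypeMatrix,
                  causal_spec: Sequence[tuple[str, float]],
                  n_cases: int, n_controls: int,
                  seed: int = 0,
                  trait: str = "disease",
                  ) -> GwasSumstats:
    """Case-control GWAS over the genotype panel's variants.

    A cohort of ``n_cases + n_controls`` individuals is built by
    bootstrap-resampling rows of ``geno`` (preserving LD and allele
    frequencies), case status is drawn from a logistic liability with
    the requested per-variant log-odds, and per-variant effect sizes
    come from the score test — ``beta = U/V``, ``se = V^{-1/2}`` with
    ``U = g'(y - ybar)`` and ``V = ybar(1-ybar) * sum (g - gbar)^2``.
    """
    if n_cases < 50 or n_controls < 50:
        raise ValueError("need at least 50 cases and 50 controls")
    panel = {v: i for i, v in enumerate(geno.variant_ids)}
    for vid, _ in causal_spec:
        if vid not in panel:
            raise ValueError(f"causal variant {vid!r} not in genotype panel")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_total = n_cases + n_controls
    prev = n_cases / n_total
    alpha = np.log(prev / (1 - prev))

    pool_factor = 3
    for _ in range(6):
        pool_n = pool_factor * n_total
        rows = rng.integers(0, geno.n_samples, size=pool_n)
        G = geno.dosages[rows]
        score = np.zeros(pool_n)
        for vid, logodds in causal_spec:
            g = G[:, panel[vid]]
            score += logodds * (g - g.mean())
        pcase = 1.0 / (1.0 + np.exp(-(alpha + score)))
        y = (rng.random(pool_n) < pcase).astype(float)
        case_idx = np.flatnonzero(y == 1)
        ctrl_idx = np.flatnonzero(y == 0)
        if len(case_idx) >= n_cases and len(ctrl_idx) >= n_controls:
            break
        pool_factor *= 2
    else:  # pragma: no cover - pathological prevalence
        raise RuntimeError("could not assemble requested case/control counts")

    keep = np.concatenate([rng.choice(case_idx, n_cases, replace=False),
                           rng.choice(ctrl_idx, n_controls, replace=False)])
    G = G[keep]
    y = y[keep]

    beta, se, p, ok = logistic_score_test(G, y)

    tab = pd.DataFrame({
        "variant": geno.variant_ids,
        "chrom": [v.chrom for v in geno.variants],
        "pos": [v.pos for v in geno.variants],
        "ref": [v.ref for v in geno.variants],
        "alt": [v.alt for v in geno.variants],
        "beta": beta, "se": se, "p": p,
        "n": n_total,
    })
    tab = tab[ok].reset_index(drop=True)  # drop monomorphic columns
    return GwasSumstats(table=tab, trait=trait, ancestry=geno.ancestry,
                        n_cases=n_cases, n_controls=n_controls)
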