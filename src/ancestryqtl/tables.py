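"""Plain-text tabular I/O.

Everything the pipeline reads or writes is tab-delimited with a header
(genotype dosages, variant/feature metadata, traits, covariates,
summary statistics) except LD blocks, which are also accepted as BED
(0-based half-open, converted to the internal 1-based half-open
convention on read).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .containers import (GenotypeMatrix, GwasSumstats, LDBlock, TraitMatrix,
                         VariantRecord, make_variant_id, parse_variant_id)

__all__ = [
    "write_genotypes", "read_genotypes",
    "write_traits", "read_traits",
    "write_covariates", "read_covariates",
    "write_sumstats", "read_sumstats",
    "write_blocks", "read_bed_blocks",
    "read_yaml_config",
]


def write_genotypes(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.dosages.tsv`` (samples × variants) and
    ``<prefix>.variants.tsv`` (variant metadata)."""
    prefix = Path(prefix)
    pd.DataFrame(geno.dosages, index=geno.samples, columns=geno.variant_ids) \
        .to_csv(f"{prefix}.dosages.tsv", sep="\t", index_label="sample")
    pd.DataFrame([{
        "variant": v.id, "chrom": v.chrom, "pos": v.pos,
        "ref": v.ref, "alt": v.alt,
        "maf_afr": v.maf_afr, "maf_eur": v.maf_eur,
        "ld_block": -1 if v.ld_block is None else v.ld_block,
    } for v in geno.variants]).to_csv(f"{prefix}.variants.tsv", sep="\t", index=False)


def read_genotypes(prefix: str | Path, ancestry: str = "") -> GenotypeMatrix:
    prefix = Path(prefix)
    dos = pd.read_csv(f"{prefix}.dosages.tsv", sep="\t", index_col="sample")
    meta = pd.read_csv(f"{prefix}.variants.tsv", sep="\t")
    variants = [VariantRecord.from_id(
        r.variant, maf_afr=r.maf_afr, maf_eur=r.maf_eur,
        ld_block=None if r.ld_block < 0 else int(r.ld_block))
        for r in meta.itertuples()]
    return GenotypeMatrix(samples=list(dos.index), variants=variants,
                          dosages=dos.to_numpy(), ancestry=ancestry)


def write_traits(traits: TraitMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    traits.to_frame().to_csv(f"{prefix}.values.tsv", sep="\t",
                             index_label="sample")
    traits.features.to_csv(f"{prefix}.features.tsv", sep="\t", index=False)


def read_traits(prefix: str | Path) -> TraitMatrix:
    prefix = Path(prefix)
    vals = pd.read_csv(f"{prefix}.values.tsv", sep="\t", index_col="sample")
    feats = pd.read_csv(f"{prefix}.features.tsv", sep="\t")
    return TraitMatrix(samples=list(vals.index), features=feats,
                       values=vals.to_numpy())


def write_covariates(cov: pd.DataFrame, path: str | Path) -> None:
    cov.to_csv(path, sep="\t", index=False)


def read_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sumstats(gwas: GwasSumstats, path: str | Path) -> None:
    tab = gwas.table.copy()
    tab.insert(0, "trait", gwas.trait)
    tab.insert(1, "ancestry", gwas.ancestry)
    tab.to_csv(path, sep="\t", index=False)


#: maps a foreign header to the internal one, e.g. {"SNP": "variant"}
DEFAULT_DIALECT: dict[str, str] = {}


def read_sumstats(path: str | Path,
                  dialect: Optional[dict[str, str]] = None,
                  n_cases: int = 0, n_controls: int = 0
                  ) -> tuple[GwasSumstats, int]:
    """Read a GWAS summary table; returns (sumstats, n_dropped_rows).

    Required columns after applying the dialect rename: variant, beta,
    se, p.  Variant ids are validated as chr:pos:ref:alt; rows with
    malformed ids or non-finite beta/se are dropped and counted.
    """
    tab = pd.read_csv(path, sep="\t")
    if dialect:
        tab = tab.rename(columns=dialect)
    for col in ("variant", "beta", "se", "p"):
        if col not in tab.columns:
            raise ValueError(f"sumstats file {path} missing required column {col!r}")

    n0 = len(tab)
    tab["beta"] = pd.to_numeric(tab["beta"], errors="coerce")
    tab["se"] = pd.to_numeric(tab["se"], errors="coerce")
    ok = np.isfinite(tab["beta"]) & np.isfinite(tab["se"]) & (tab["se"] > 0)

    def _norm(vid) -> Optional[str]:
        try:
            chrom, pos, ref, alt = parse_variant_id(str(vid))
        except (ValueError, TypeError):
            return None
        return make_variant_id(chrom, pos, ref, alt)

    norm = tab["variant"].map(_norm)
    ok &= norm.notna()
    tab = tab[ok].copy()
    tab["variant"] = norm[ok]
    if "chrom" not in tab.columns:
        parsed = tab["variant"].map(parse_variant_id)
        tab["chrom"] = [p[0] for p in parsed]
        tab["pos"] = [p[1] for p in parsed]
    trait = str(tab["trait"].iloc[0]) if "trait" in tab.columns and len(tab) else "trait"
    ancestry = str(tab["ancestry"].iloc[0]) if "ancestry" in tab.columns and len(tab) else ""
    keep = [c for c in ("variant", "chrom", "pos", "ref", "alt", "beta", "se",
                        "p", "n") if c in tab.columns]
    gs = GwasSumstats(table=tab[keep].reset_index(drop=True), trait=trait,
                      ancestry=ancestry, n_cases=n_cases, n_controls=n_controls)
    return gs, n0 - len(tab)


def write_blocks(blocks: list[LDBlock], path: str | Path) -> None:
    """Write LD blocks as BED: 0-based half-open, one interval per line."""
    with open(path, "w") as fh:
        for b in sorted(blocks, key=lambda b: (b.chrom, b.start)):
            fh.write(f"{b.chrom}\t{b.start - 1}\t{b.end - 1}\t{b.index}\n")


def read_bed_blocks(path: str | Path) -> list[LDBlock]:
    """Read BED intervals into the internal 1-based half-open convention.

    A BED record [s, e) on 0-based coordinates covers 1-based positions
    s+1 .. e, i.e. the internal interval [s+1, e+1).
    """
    blocks = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            index = int(parts[3]) if len(parts) > 3 else i
            blocks.append(LDBlock(chrom=chrom, start=start0 + 1,
                                  end=end0 + 1, index=index))
    return blocks


def read_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg
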