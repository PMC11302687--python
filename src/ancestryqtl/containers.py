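"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* Variant identifiers are ``chr:pos:ref:alt`` strings with 1-based
  positions (e.g. ``chr11:116780399:C:T``).
* Dosages count copies of the minor allele within the ancestry the
  matrix belongs to, so values lie in ``[0, 2]`` and minor-allele
  frequency is half the column mean.
* LD blocks are half-open ``[start, end)`` intervals on 1-based
  coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "TraitMatrix",
    "EffectSpec",
    "GwasSumstats",
    "LDBlock",
    "ThresholdSpec",
    "parse_variant_id",
    "make_variant_id",
]


def make_variant_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{int(pos)}:{ref}:{alt}"


def parse_variant_id(vid: str) -> tuple[str, int, str, str]:
    """Split ``chr:pos:ref:alt`` into its four components.

    Raises ``ValueError`` on malformed ids (wrong arity, non-integer or
    non-positive position).
    """
    parts = vid.split(":")
    if len(parts) != 4:
        raise ValueError(f"variant id {vid!r} is not chr:pos:ref:alt")
    chrom, pos_s, ref, alt = parts
    pos = int(pos_s)
    if pos < 1:
        raise ValueError(f"variant id {vid!r} has non-positive position")
    if not ref or not alt:
        raise ValueError(f"variant id {vid!r} has empty alleles")
    return chrom, pos, ref, alt


@dataclass
class VariantRecord:
    """One biallelic variant with per-ancestry minor-allele frequencies."""

    id: str
    chrom: str
    pos: int
    maf_afr: float
    maf_eur: float
    ld_block: Optional[int] = None

    def __post_init__(self) -> None:
        chrom, pos, _, _ = parse_variant_id(self.id)
        if chrom != self.chrom or pos != self.pos:
            raise ValueError(f"variant id {self.id!r} disagrees with chrom/pos fields")
        for name, maf in (("maf_afr", self.maf_afr), ("maf_eur", self.maf_eur)):
            if not 0.0 <= maf <= 0.5:
                raise ValueError(f"{name}={maf} outside [0, 0.5] for {self.id}")

    @property
    def ref(self) -> str:
        return self.id.split(":")[2]

    @property
    def alt(self) -> str:
        return self.id.split(":")[3]

    @classmethod
    def from_id(cls, vid: str, maf_afr: float, maf_eur: float,
                ld_block: Optional[int] = None) -> "VariantRecord":
        chrom, pos, _, _ = parse_variant_id(vid)
        return cls(id=vid, chrom=chrom, pos=pos, maf_afr=maf_afr,
                   maf_eur=maf_eur, ld_block=ld_block)


@dataclass
class GenotypeMatrix:
    """Hard-call dosage matrix for one ancestry (samples x variants)."""

    samples: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray
    ancestry: str = ""

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.samples) or m != len(self.variants):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants")
        if np.isnan(self.dosages).any():
            raise ValueError("dosage matrix contains missing entries")
        if self.dosages.min() < 0 or self.dosages.max() > 2:
            raise ValueError("dosages outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def column_maf(self) -> np.ndarray:
        """Empirical minor-allele frequency per column."""
        return self.dosages.mean(axis=0) / 2.0

    def index_of(self, vid: str) -> int:
        try:
            return self.variant_ids.index(vid)
        except ValueError:
            raise KeyError(f"variant {vid!r} not in genotype panel") from None

    def dosage_of(self, vid: str) -> np.ndarray:
        return self.dosages[:, self.index_of(vid)]

    def subset_variants(self, vids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.index_of(v) for v in vids]
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in idx],
            dosages=self.dosages[:, idx].copy(),
            ancestry=self.ancestry,
        )


# Feature-metadata columns expected on TraitMatrix.features
FEATURE_COLUMNS = ["id", "kind", "chrom", "gene_start", "super_pathway", "xenobiotic"]


@dataclass
class TraitMatrix:
    """Molecular-trait abundance matrix (samples x features), NaN = missing.

    ``features`` is a DataFrame with columns ``id`` (unique), ``kind``
    ('protein'|'metabolite'), ``chrom``/``gene_start`` (proteins: coding-gene
    location for the cis window), ``super_pathway`` and ``xenobiotic``
    (metabolites).
    """

    samples: list[str]
    features: pd.DataFrame
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.features = self.features.reset_index(drop=True)
        n, m = self.values.shape
        if n != len(self.samples) or m != len(self.features):
            raise ValueError("trait matrix shape mismatch")
        ids = self.features["id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        prot = self.features[self.features["kind"] == "protein"]
        if "gene_start" in prot.columns and prot["gene_start"].isna().any():
            raise ValueError("protein features must carry a gene start")
        met = self.features[self.features["kind"] == "metabolite"]
        if "super_pathway" in met.columns and met["super_pathway"].isna().any():
            raise ValueError("metabolite features must carry a super-pathway")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def feature_ids(self) -> list[str]:
        return self.features["id"].tolist()

    def column(self, feature_id: str) -> np.ndarray:
        loc = self.features.index[self.features["id"] == feature_id]
        if len(loc) == 0:
            raise KeyError(f"feature {feature_id!r} not present")
        return self.values[:, loc[0]]

    def copy(self) -> "TraitMatrix":
        return TraitMatrix(samples=list(self.samples),
                           features=self.features.copy(),
                           values=self.values.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples,
                            columns=self.feature_ids)


@dataclass(frozen=True)
class EffectSpec:
    """Planted genotype->trait effect (the simulation ground truth)."""

    feature: str
    variant: str
    beta_afr: float
    beta_eur: float
    cis: bool = True

    def __post_init__(self) -> None:
        for b in (self.beta_afr, self.beta_eur):
            if abs(b) >= 5:
                raise ValueError("|beta| must be < 5 on the standardized-trait scale")


@dataclass
class GwasSumstats:
    """Case-control GWAS summary statistics for one trait and ancestry.

    ``table`` columns: variant, chrom, pos, ref, alt, beta, se, p, n.
    """

    table: pd.DataFrame
    trait: str = "trait"
    ancestry: str = ""
    n_cases: int = 0
    n_controls: int = 0

    REQUIRED = ("variant", "beta", "se", "p")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"sumstats table missing columns: {missing}")
        if (self.table["se"] <= 0).any():
            raise ValueError("sumstats contain non-positive standard errors")
        self.table = self.table.reset_index(drop=True)

    @property
    def z(self) -> np.ndarray:
        return (self.table["beta"] / self.table["se"]).to_numpy()

    def subset(self, vids: Sequence[str]) -> "GwasSumstats":
        sub = self.table[self.table["variant"].isin(set(vids))].copy()
        return GwasSumstats(table=sub, trait=self.trait, ancestry=self.ancestry,
                            n_cases=self.n_cases, n_controls=self.n_controls)


@dataclass(frozen=True)
class LDBlock:
    """Approximately independent genomic interval, half-open [start, end)."""

    chrom: str
    start: int
    end: int
    index: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"LD block {self.index}: end {self.end} <= start {self.start}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class ThresholdSpec:
    """Study-wide significance threshold derived from genome-wide 5e-8."""

    genome_wide: float
    n_components: int
    study_wide: float

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.study_wide > self.genome_wide:
            raise ValueError("study-wide threshold must not exceed genome-wide")
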