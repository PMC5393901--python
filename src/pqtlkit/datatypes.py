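"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* genomic coordinates are 1-based inclusive;
* genotype dosages are expected counts of the *coded* allele in [0, 2],
  with ``NaN`` as the (out-of-band) missing sentinel;
* protein levels are on the log10 scale, expression on log2;
* all effect sizes (betas) are per copy of the coded allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Input violates a documented invariant (bad value, bad shape)."""


class FormatError(ValueError):
    """File cannot be parsed under the declared dialect."""


@dataclass(frozen=True)
class Variant:
    """A single (typically imputed) variant with its coded-allele convention."""

    id: str
    chrom: str
    pos: int
    coded_allele: str
    other_allele: str
    coded_freq: Optional[float] = None
    missense: bool = False
    impute_rsq: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"{self.id}: pos must be >= 1, got {self.pos}")
        if self.coded_allele == self.other_allele:
            raise ValidationError(f"{self.id}: coded and other allele identical")
        if self.coded_freq is not None and not (0.0 <= self.coded_freq <= 1.0):
            raise ValidationError(f"{self.id}: coded_freq outside [0, 1]")


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix.

    ``dosage[i, j]`` is the expected coded-allele count of sample ``i`` at
    variant ``j``; missing entries are NaN.
    """

    samples: list[str]
    variants: list[Variant]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.samples)}, {len(self.variants)})"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 2)
        if np.any(bad):
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"dosage {self.dosage[i, j]} outside [0, 2] at sample "
                f"{self.samples[i]!r}, variant {self.variants[j].id!r}"
            )
        self._index = {v.id: k for k, v in enumerate(self.variants)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in matrix") from None

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosage[:, self.variant_index(variant_id)]

    def call_rates(self) -> np.ndarray:
        """Fraction of non-missing dosages per variant."""
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def subset_variants(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[k] for k in keep],
            dosage=self.dosage[:, keep].copy(),
        )

    def subset_samples(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            samples=[self.samples[k] for k in keep],
            variants=list(self.variants),
            dosage=self.dosage[keep, :].copy(),
        )


@dataclass
class ProteinPanel:
    """Samples x assays protein matrix (log10 scale) plus per-assay QC metadata."""

    samples: list[str]
    proteins: list[str]
    values: np.ndarray
    frac_below_lod: dict[str, float]
    cv_interplate: dict[str, float]
    plate_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.proteins)):
            raise ValidationError(
                f"values shape {self.values.shape} != "
                f"({len(self.samples)}, {len(self.proteins)})"
            )
        for name, d in (("frac_below_lod", self.frac_below_lod),
                        ("cv_interplate", self.cv_interplate)):
            for assay, v in d.items():
                if not (0.0 <= v <= 1.0):
                    raise ValidationError(f"{name}[{assay!r}] = {v} outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.proteins)

    def subset_proteins(self, keep: Sequence[str]) -> "ProteinPanel":
        idx = [self.proteins.index(p) for p in keep]
        return ProteinPanel(
            samples=list(self.samples),
            proteins=list(keep),
            values=self.values[:, idx].copy(),
            frac_below_lod={p: self.frac_below_lod[p] for p in keep},
            cv_interplate={p: self.cv_interplate[p] for p in keep},
            plate_of=dict(self.plate_of),
        )


@dataclass(frozen=True)
class GeneModel:
    """Gene body on the reference, 1-based inclusive coordinates."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"{self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class AssocRecord:
    """One (variant, trait) linear-association result."""

    variant: Variant
    trait: str
    beta: float
    se: float
    p: float
    n: int
    r2_explained: float
    p_underflowed: bool = False


@dataclass
class PqtlLocus:
    """An index signal with the correlated signals merged into it."""

    index: AssocRecord
    members: list[AssocRecord]
    locus_class: Optional[str] = None  # "cis" | "trans" | "ambiguous"
    distance_kb: Optional[float] = None


@dataclass
class EqtlDataset:
    """One expression dataset: log2 expression and matching genotypes."""

    name: str
    expression: pd.DataFrame  # samples x genes
    genotypes: GenotypeMatrix

    def __post_init__(self) -> None:
        if list(self.expression.index) != list(self.genotypes.samples):
            raise ValidationError(f"{self.name}: expression/genotype samples differ")
        if self.n < 30:
            raise ValidationError(f"{self.name}: n = {self.n} < 30")

    @property
    def n(self) -> int:
        return len(self.expression.index)

    @property
    def genes(self) -> list[str]:
        return list(self.expression.columns)


@dataclass
class MetaResult:
    """Fixed-effects meta-analysis of one variant-trait pair across cohorts."""

    trait: str
    variant_id: str
    cohort_estimates: list[tuple[Optional[float], Optional[float], Optional[int]]]
    pooled_beta: float
    pooled_se: float
    pooled_p: float
    direction: str


@dataclass
class NodeScoreMap:
    """Per-gene trans-eQTL weight for the weighted path test.

    Scores are 1 (no trans-eQTL evidence), 0.8 (best p < 0.05) or
    0.6 (best p < 0.005).
    """

    scores: dict[str, float]
    provenance: dict[str, tuple[float, str]] = field(default_factory=dict)

    def score(self, gene: str) -> float:
        return self.scores.get(gene, 1.0)


@dataclass
class PathResult:
    """Shortest-path result between a cis-gene and a trait gene."""

    source: str
    target: str
    nodes: list[str]                     # unweighted shortest path, [] if disconnected
    unweighted_len: float                # edge count, inf when disconnected
    weighted_len: float                  # sum of entered-node scores, inf if disconnected
    weighted_nodes: list[str] = field(default_factory=list)
    perm_p_unweighted: Optional[float] = None
    perm_p_weighted: Optional[float] = None


@dataclass
class EvidenceRow:
    """All five evidence tracks for one (index SNP, candidate cis-gene) pair."""

    trait: str
    index_snp: str
    cis_gene: str
    distance_kb: float
    dist_rank: int
    coding_proxy: Optional[tuple[str, float]] = None
    cis_eqtl_hits: list[tuple[str, float]] = field(default_factory=list)
    unweighted_path_sig: bool = False
    unweighted_perm_p: Optional[float] = None
    weighted_path: Optional[tuple[str, float]] = None
    literature_score: Optional[int] = None

    def criteria_fired(self, lit_min: int = 50) -> list[str]:
        fired = []
        if self.coding_proxy is not None:
            fired.append("coding_proxy")
        if self.cis_eqtl_hits:
            fired.append("cis_eqtl")
        if self.unweighted_path_sig:
            fired.append("unweighted_path")
        if self.weighted_path is not None:
            fired.append("weighted_path")
        if self.literature_score is not None and self.literature_score > lit_min:
            fired.append("literature")
        return fired
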