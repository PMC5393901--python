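"""Pleiotropy clustering and pooled disease risk scores.

Pleiotropy: index SNPs with at least two protein associations below a
Bonferroni cutoff of 0.05/(n_proteins * n_snps) are collected into a
-log10(p) matrix and ordered by complete-linkage hierarchical clustering
with 1 - Pearson correlation as the distance.

Risk scores: each protein's index SNPs are looked up in a disease GWAS,
alleles harmonized so the coded allele increases disease risk (palindromic
A/T and C/G pairs excluded), the per-SNP effects pooled by inverse-variance
weighting, and the pooled p-values flagged by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests

from .datatypes import ValidationError
from .replication import ivw_meta

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# pleiotropy
# ---------------------------------------------------------------------------


@dataclass
class PleiotropyMatrix:
    """-log10 p matrix of retained index SNPs x proteins."""

    matrix: pd.DataFrame
    alpha: float
    row_order: Optional[list[str]] = None
    col_order: Optional[list[str]] = None
    row_linkage: Optional[np.ndarray] = None
    col_linkage: Optional[np.ndarray] = None


def pleiotropy_select(assoc_p: pd.DataFrame, n_snps: int, n_proteins: int,
                      base_alpha: float = 0.05) -> PleiotropyMatrix:
    """Select pleiotropic index SNPs.

    ``assoc_p`` holds p-values with SNPs as rows and proteins as columns.
    alpha = base_alpha/(n_proteins * n_snps); SNPs with >= 2 sub-alpha
    protein associations are retained, and proteins with no retained
    sub-alpha association are dropped.
    """
    if n_snps < 1 or n_proteins < 1:
        raise ValidationError("n_snps and n_proteins must be >= 1")
    alpha = base_alpha / (n_proteins * n_snps)
    sig = assoc_p < alpha
    keep_snps = sig.sum(axis=1) >= 2
    sub = assoc_p.loc[keep_snps]
    keep_prot = (sub < alpha).any(axis=0)
    sub = sub.loc[:, keep_prot]
    return PleiotropyMatrix(matrix=-np.log10(sub), alpha=alpha)


def _pearson_condensed(rows: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance; zero-variance profiles get r = 0."""
    n = rows.shape[0]
    sds = rows.std(axis=1)
    zero_var = sds == 0
    if zero_var.any():
        logger.info("zero-variance profiles at rows %s; distance set to 1",
                    np.where(zero_var)[0].tolist())
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            if zero_var[i] or zero_var[j]:
                r = 0.0
            else:
                r = float(np.corrcoef(rows[i], rows[j])[0, 1])
            out.append(1.0 - r)
    return np.asarray(out)


def cluster_matrix(m: PleiotropyMatrix) -> PleiotropyMatrix:
    """Order rows and columns by complete-linkage clustering on
    1 - Pearson distances of the -log10 p profiles."""
    mat = m.matrix
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValidationError("clustering needs >= 2 rows and >= 2 columns")
    vals = mat.to_numpy(dtype=float)
    row_z = linkage(_pearson_condensed(vals), method="complete")
    col_z = linkage(_pearson_condensed(vals.T), method="complete")
    row_order = [mat.index[k] for k in leaves_list(row_z)]
    col_order = [mat.columns[k] for k in leaves_list(col_z)]
    return PleiotropyMatrix(matrix=mat.loc[row_order, col_order],
                            alpha=m.alpha, row_order=row_order,
                            col_order=col_order, row_linkage=row_z,
                            col_linkage=col_z)


# ---------------------------------------------------------------------------
# risk-score harmonization and pooling
# ---------------------------------------------------------------------------

_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class AlignedRecord:
    """A disease-GWAS record aligned so the coded allele raises risk."""

    variant_id: str
    coded_allele: str
    other_allele: str
    beta: float
    se: float
    flipped_alleles: bool = False
    flipped_sign: bool = False


def harmonize_to_risk(pqtl: dict, disease: dict) -> Optional[AlignedRecord]:
    """Align a disease record to a pQTL record and to the risk direction.

    Both records need keys ``coded_allele``/``other_allele`` plus ``beta``
    and (disease) ``se``. Allele pairs must match possibly swapped (swap
    flips the beta sign); then the coded allele is flipped if needed so the
    disease beta is >= 0. Palindromic A/T and C/G pairs and mismatched
    pairs are excluded (None, with a warning logged). Idempotent.
    """
    pa = (pqtl["coded_allele"].upper(), pqtl["other_allele"].upper())
    da = (disease["coded_allele"].upper(), disease["other_allele"].upper())
    vid = disease.get("id", pqtl.get("id", "?"))
    if frozenset(pa) in _PALINDROMIC:
        logger.warning("%s: strand-ambiguous %s/%s pair excluded", vid, *pa)
        return None
    beta = float(disease["beta"])
    flipped_alleles = False
    if da == pa:
        coded, other = da
    elif (da[1], da[0]) == pa:
        coded, other = da[1], da[0]
        beta = -beta
        flipped_alleles = True
    else:
        logger.warning("%s: allele pair %s/%s does not match %s/%s; excluded",
                       vid, *da, *pa)
        return None
    flipped_sign = False
    if beta < 0:
        coded, other = other, coded
        beta = -beta
        flipped_sign = True
    return AlignedRecord(variant_id=str(vid), coded_allele=coded,
                         other_allele=other, beta=beta,
                         se=float(disease["se"]),
                         flipped_alleles=flipped_alleles,
                         flipped_sign=flipped_sign)


@dataclass
class RiskScoreResult:
    protein: str
    records: list[AlignedRecord]
    pooled_beta: float
    pooled_se: float
    pooled_p: float
    fdr_significant: Optional[bool] = None


def pooled_score(protein: str, records: Sequence[AlignedRecord]
                 ) -> RiskScoreResult:
    """Inverse-variance pooled disease effect of one protein's risk-aligned
    variants (records are assumed LD-independent upstream)."""
    if not records:
        raise ValidationError(f"{protein}: no records to pool")
    if any(r.beta < 0 for r in records):
        raise ValidationError(f"{protein}: records must be risk-aligned first")
    beta, se, p, _ = ivw_meta([(r.beta, r.se) for r in records])
    return RiskScoreResult(protein=protein, records=list(records),
                           pooled_beta=beta, pooled_se=se, pooled_p=p)


def bh_fdr(pvals: Sequence[float], q: float = 0.05
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    pvals = np.asarray(list(pvals), dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    reject, adjusted, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject, adjusted


def flag_risk_scores(results: Sequence[RiskScoreResult], q: float = 0.05
                     ) -> list[RiskScoreResult]:
    """FDR-flag pooled scores as one family."""
    if not results:
        return []
    reject, _ = bh_fdr([r.pooled_p for r in results], q)
    for r, flag in zip(results, reject):
        r.fdr_significant = bool(flag)
    return list(results)


def risk_score_table(results: Sequence[RiskScoreResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "protein": r.protein,
            "n_snps": len(r.records),
            "snps": ",".join(rec.variant_id for rec in r.records),
            "beta_pool": r.pooled_beta,
            "se_pool": r.pooled_se,
            "p_pool": r.pooled_p,
            "fdr_significant": r.fdr_significant,
        }
        for r in results
    ])
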