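"""Replication of discovery pQTLs in external cohorts.

Index SNPs are matched into each replication cohort directly by id or via
an LD proxy (r² > 0.8 within ±500 kb on the same chromosome); per-cohort
estimates are combined by fixed-effects inverse-variance weighting (the
METAL beta/se scheme), and each locus is assigned a replication status
using a Bonferroni threshold of 0.05 divided by the number of measurable
pQTLs, rounded to one significant figure (0.05/71 -> 0.0007).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .datatypes import GenotypeMatrix, MetaResult, PqtlLocus, Variant
from .assoc import ld_r2
from .io import P_FLOOR

#: default replication cohort sizes (three community cohorts, total 2,639)
REPLICATION_COHORT_N = (976, 933, 730)

PROXY_WINDOW_KB = 500.0


def replication_n(cohort_sizes: Sequence[int] = REPLICATION_COHORT_N) -> int:
    """Total replication sample size across cohorts."""
    return int(sum(cohort_sizes))


def find_proxy(index: Variant, cohort_variants: Sequence[str],
               ld_ref: GenotypeMatrix, proxy_r2: float = 0.8
               ) -> Optional[tuple[Variant, float, int]]:
    """Match an index variant into a cohort, directly or by LD proxy.

    Returns (variant, r², ld_sign) or None. ld_sign is the sign of the
    dosage correlation in the LD reference, used to harmonize the proxy's
    effect direction; it is +1 for a direct match.
    """
    cohort_set = set(cohort_variants)
    if index.id in cohort_set:
        return index, 1.0, 1
    best: Optional[tuple[Variant, float, int]] = None
    best_key = None
    a = ld_ref.column(index.id)
    for v in ld_ref.variants:
        if v.id not in cohort_set or v.id == index.id:
            continue
        if v.chrom != index.chrom:
            continue
        if abs(v.pos - index.pos) > PROXY_WINDOW_KB * 1000:
            continue
        b = ld_ref.column(v.id)
        mask = ~np.isnan(a) & ~np.isnan(b)
        if mask.sum() < 2 or a[mask].std() == 0 or b[mask].std() == 0:
            continue
        r = float(np.corrcoef(a[mask], b[mask])[0, 1])
        r2 = r * r
        if r2 <= proxy_r2:
            continue
        key = (-r2, abs(v.pos - index.pos), v.id)
        if best_key is None or key < best_key:
            best_key = key
            best = (v, r2, 1 if r >= 0 else -1)
    return best


def ivw_meta(estimates: Sequence[tuple[Optional[float], Optional[float]]]
             ) -> tuple[float, float, float, str]:
    """Inverse-variance fixed-effects pooling.

    ``estimates`` is one (beta, se) per cohort in fixed order; a cohort with
    no estimate contributes '?' to the direction string and nothing to the
    pool. Returns (pooled_beta, pooled_se, pooled_p, direction).
    """
    betas, ses, direction = [], [], []
    for est in estimates:
        if est is None or est[0] is None or est[1] is None:
            direction.append("?")
            continue
        beta, se = float(est[0]), float(est[1])
        if se <= 0:
            raise ValueError("standard errors must be positive")
        betas.append(beta)
        ses.append(se)
        direction.append("+" if beta > 0 else "-" if beta < 0 else "?")
    if not betas:
        raise ValueError("no usable estimates to pool")
    w = 1.0 / np.asarray(ses) ** 2
    pooled_se = float(1.0 / np.sqrt(w.sum()))
    pooled_beta = float((w * np.asarray(betas)).sum() * pooled_se ** 2)
    z = pooled_beta / pooled_se
    pooled_p = max(2.0 * float(norm.sf(abs(z))), P_FLOOR)
    return pooled_beta, pooled_se, pooled_p, "".join(direction)


def meta_analyze(trait: str, variant_id: str,
                 cohort_estimates: Sequence[tuple[Optional[float],
                                                  Optional[float],
                                                  Optional[int]]]) -> MetaResult:
    pooled_beta, pooled_se, pooled_p, direction = ivw_meta(
        [(e[0], e[1]) if e is not None else None for e in cohort_estimates]
    )
    return MetaResult(
        trait=trait, variant_id=variant_id,
        cohort_estimates=list(cohort_estimates),
        pooled_beta=pooled_beta, pooled_se=pooled_se, pooled_p=pooled_p,
        direction=direction,
    )


def bonferroni_threshold(n_measurable: int, alpha: float = 0.05) -> float:
    """alpha/n rounded to one significant figure (0.05/71 -> 0.0007)."""
    if n_measurable < 1:
        raise ValueError("n_measurable must be >= 1")
    raw = alpha / n_measurable
    return float(f"{raw:.0e}")


def replication_status(discovery: PqtlLocus, meta: Optional[MetaResult],
                       n_measurable: int, nominal_p: float = 0.05) -> str:
    """Assign one of replicated_bonferroni / replicated_nominal /
    not_replicated / not_measured.

    Either replicated status additionally requires the pooled effect sign to
    agree with the discovery sign.
    """
    if meta is None:
        return "not_measured"
    if n_measurable < 1:
        raise ValueError("n_measurable must be >= 1 when meta is present")
    concordant = np.sign(meta.pooled_beta) == np.sign(discovery.index.beta)
    if concordant and meta.pooled_p < bonferroni_threshold(n_measurable):
        return "replicated_bonferroni"
    if concordant and meta.pooled_p < nominal_p:
        return "replicated_nominal"
    return "not_replicated"
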