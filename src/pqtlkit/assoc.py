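"""Discovery scan: assay/variant QC, residualization, Wald tests, locus
merging and cis/trans classification.

The scan mirrors a standard two-step pQTL protocol: protein levels (log10)
are first residualized on clinical covariates and standardized, then each
(protein, variant) pair is tested by simple linear regression of the
standardized residual on the coded-allele dosage (a Wald test on the slope
with a t reference at n-2 df). Genome-wide significant records are merged
into loci by greedy LD blocking (R² > merge_r2 AND distance <= merge window)
and classified as cis (within 500 kb of the trait gene), trans (other
chromosome or >= 100 Mb) or ambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    AssocRecord,
    GeneModel,
    GenotypeMatrix,
    PqtlLocus,
    ProteinPanel,
    ValidationError,
)
from .io import P_FLOOR


@dataclass
class QcLog:
    """Which QC rule removed which assay/variant."""

    removed: list[tuple[str, str]] = field(default_factory=list)

    def add(self, item: str, reason: str) -> None:
        self.removed.append((item, reason))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def qc_proteins(panel: ProteinPanel, lod_frac: float = 0.20,
                cv_max: float = 0.25) -> tuple[ProteinPanel, QcLog]:
    """Drop assays with > lod_frac of samples below the detection limit or
    inter-plate CV > cv_max (both comparisons strict)."""
    log = QcLog()
    keep = []
    for p in panel.proteins:
        if p not in panel.frac_below_lod or p not in panel.cv_interplate:
            raise ValidationError(f"assay {p!r} lacks QC metadata")
        if panel.frac_below_lod[p] > lod_frac:
            log.add(p, "lod")
        elif panel.cv_interplate[p] > cv_max:
            log.add(p, "cv")
        else:
            keep.append(p)
    return panel.subset_proteins(keep), log


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test.

    p is the sum of conditional probabilities (given allele counts) of all
    heterozygote counts whose probability does not exceed that of the
    observed count. All-zero counts return 1 by convention.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or c != int(c):
            raise ValidationError("genotype counts must be nonnegative integers")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return 1.0
    n_a = 2 * n_aa + n_Aa  # minor-allele count, by relabeling below
    n_A = 2 * n_AA + n_Aa
    rare = min(n_A, n_a)
    if rare == 0:
        return 1.0
    # log-probability of h heterozygotes given allele counts:
    # P(h) = n! rare! common! 2^h / ((rare-h)/2)! h! ((common-h)/2)! (2n)!
    common = 2 * n - rare
    hs = np.arange(rare % 2, rare + 1, 2)
    lg = math.lgamma
    base = lg(n + 1) + lg(rare + 1) + lg(common + 1) - lg(2 * n + 1)
    logp = np.array([
        base + h * math.log(2.0)
        - lg((rare - h) // 2 + 1) - lg(h + 1) - lg((common - h) // 2 + 1)
        for h in hs
    ])
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = n_Aa
    p_obs = probs[np.where(hs == obs)[0][0]]
    # tolerance guards against fp ties in the <= comparison
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def qc_genotypes(gm: GenotypeMatrix, hwe_p: float = 1e-6,
                 call_rate: float = 0.95) -> tuple[GenotypeMatrix, QcLog]:
    """Drop variants with call rate < call_rate or HWE exact p < hwe_p.

    HWE is evaluated on hard calls obtained by rounding dosages to the
    nearest integer count.
    """
    log = QcLog()
    keep = []
    rates = gm.call_rates()
    for j, v in enumerate(gm.variants):
        if rates[j] < call_rate:
            log.add(v.id, "call_rate")
            continue
        col = gm.dosage[:, j]
        hard = np.rint(col[~np.isnan(col)]).astype(int)
        hard = np.clip(hard, 0, 2)
        n_aa, n_Aa, n_AA = ((hard == 0).sum(), (hard == 1).sum(),
                            (hard == 2).sum())
        if hwe_exact_test(int(n_AA), int(n_Aa), int(n_aa)) < hwe_p:
            log.add(v.id, "hwe")
            continue
        keep.append(j)
    return gm.subset_variants(keep), log


# ---------------------------------------------------------------------------
# residualization
# ---------------------------------------------------------------------------

_CATEGORICAL = ("centre", "batch", "plate")


def _design_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols: list[pd.Series] = []
    names: list[str] = []
    for c in covariates.columns:
        s = covariates[c]
        if c in _CATEGORICAL or s.dtype == object or isinstance(
                s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=c, drop_first=True, dtype=float)
            for dc in dummies.columns:
                cols.append(dummies[dc])
                names.append(str(dc))
        else:
            cols.append(s.astype(float))
            names.append(str(c))
    X = np.column_stack([np.ones(len(covariates))] + [c.to_numpy() for c in cols])
    names = ["intercept"] + names
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns via pivoted QR on the correlation structure
        _, r = np.linalg.qr(X)
        dep = [names[k] for k in range(X.shape[1]) if abs(r[k, k]) < 1e-8]
        raise ValidationError(f"rank-deficient covariate design; "
                              f"collinear columns: {dep or names}")
    return X, names


def residualize(panel: ProteinPanel, covariates: pd.DataFrame) -> pd.DataFrame:
    """OLS-residualize each protein on the covariates and standardize.

    Categorical covariates (centre, batch, plate, any object/categorical
    dtype) are expanded to indicator contrasts. Samples with a missing
    protein value are excluded pairwise per protein; the returned matrix has
    NaN there. Residuals have mean 0 and sd 1 (ddof=1) per protein.
    """
    cov = covariates.loc[panel.samples]
    if cov.isna().any().any():
        bad = cov.columns[cov.isna().any()].tolist()
        raise ValidationError(f"missing covariate values in columns {bad}")
    X, _ = _design_matrix(cov)
    out = np.full_like(panel.values, np.nan, dtype=float)
    for k in range(len(panel.proteins)):
        y = panel.values[:, k]
        mask = ~np.isnan(y)
        if mask.sum() <= X.shape[1] + 1:
            raise ValidationError(
                f"protein {panel.proteins[k]!r}: too few non-missing samples"
            )
        beta, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
        resid = y[mask] - X[mask] @ beta
        sd = resid.std(ddof=1)
        if sd == 0:
            raise ValidationError(
                f"protein {panel.proteins[k]!r}: zero residual variance"
            )
        out[mask, k] = resid / sd
    return pd.DataFrame(out, index=panel.samples, columns=panel.proteins)


# ---------------------------------------------------------------------------
# Wald scan
# ---------------------------------------------------------------------------


def wald_scan(residuals: pd.DataFrame, gm: GenotypeMatrix,
              p_gw: float = 5e-8) -> tuple[list[AssocRecord], list[AssocRecord]]:
    """Simple-regression Wald scan of every (protein, variant) pair.

    beta = cov(g, y)/var(g); se from the residual variance with n-2 df; p
    two-sided from the t law; r2_explained is the squared sample
    correlation. Monomorphic variants are skipped. Returns (all records,
    genome-wide flagged subset at p < p_gw, strict).
    """
    if list(residuals.index) != list(gm.samples):
        raise ValidationError("samples not aligned between residuals and genotypes")
    G = gm.dosage
    Y = residuals.to_numpy()
    records: list[AssocRecord] = []
    flagged: list[AssocRecord] = []
    for k, trait in enumerate(residuals.columns):
        y = Y[:, k]
        valid = ~np.isnan(y)[:, None] & ~np.isnan(G)
        n_eff = valid.sum(axis=0).astype(float)
        gz = np.where(valid, G, 0.0)
        yz = np.where(valid, y[:, None], 0.0)
        sg = gz.sum(axis=0)
        sy = yz.sum(axis=0)
        sgg = (gz * gz).sum(axis=0)
        sgy = (gz * yz).sum(axis=0)
        syy = (yz * yz).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sxx = sgg - sg * sg / n_eff
            sxy = sgy - sg * sy / n_eff
            syy_c = syy - sy * sy / n_eff
            beta = sxy / sxx
            rss = syy_c - beta * sxy
            rss = np.maximum(rss, 0.0)
            df = n_eff - 2
            sigma2 = rss / df
            se = np.sqrt(sigma2 / sxx)
            r2 = np.where(syy_c > 0, sxy * sxy / (sxx * syy_c), np.nan)
        for j, v in enumerate(gm.variants):
            if n_eff[j] < 3 or not np.isfinite(sxx[j]) or sxx[j] <= 0:
                continue  # monomorphic or unusable; logged by callers if needed
            b = float(beta[j])
            if se[j] == 0 or not np.isfinite(se[j]):
                # perfect fit: p clamps at the smallest positive normal float
                p, underflow, s = P_FLOOR, True, 0.0
            else:
                s = float(se[j])
                t = b / s
                p = 2.0 * float(stats.t.sf(abs(t), df[j]))
                underflow = p < P_FLOOR
                p = max(p, P_FLOOR)
            rec = AssocRecord(
                variant=v, trait=str(trait), beta=b, se=s, p=p,
                n=int(n_eff[j]), r2_explained=float(min(r2[j], 1.0)),
                p_underflowed=underflow,
            )
            records.append(rec)
            if p < p_gw:
                flagged.append(rec)
    return records, flagged


def assoc_frame(records: Sequence[AssocRecord]) -> pd.DataFrame:
    """Tabular view of scan records (S1-Table shape)."""
    return pd.DataFrame(
        {
            "id": [r.variant.id for r in records],
            "chrom": [r.variant.chrom for r in records],
            "pos": [r.variant.pos for r in records],
            "coded_allele": [r.variant.coded_allele for r in records],
            "other_allele": [r.variant.other_allele for r in records],
            "coded_freq": [r.variant.coded_freq for r in records],
            "trait": [r.trait for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "p": [r.p for r in records],
            "n": [r.n for r in records],
            "r2_explained": [r.r2_explained for r in records],
        }
    )


# ---------------------------------------------------------------------------
# LD and locus merging
# ---------------------------------------------------------------------------


def ld_r2(gm: GenotypeMatrix, v1: str, v2: str) -> Optional[float]:
    """Squared Pearson correlation of dosages over jointly non-missing
    samples; None when either variant is monomorphic there (callers treat
    as 0)."""
    a = gm.column(v1)
    b = gm.column(v2)
    mask = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[mask], b[mask]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return None
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def merge_loci(flagged: Sequence[AssocRecord], merge_r2: float,
               merge_window_kb: float, gm: GenotypeMatrix) -> dict[str, list[PqtlLocus]]:
    """Greedy LD blocking per trait: repeatedly take the best remaining
    record as index and absorb records with r² > merge_r2 AND distance
    within merge_window_kb on the same chromosome. Deterministic
    (ties by variant id) and idempotent."""
    by_trait: dict[str, list[AssocRecord]] = {}
    for rec in flagged:
        by_trait.setdefault(rec.trait, []).append(rec)
    out: dict[str, list[PqtlLocus]] = {}
    for trait, recs in by_trait.items():
        remaining = sorted(recs, key=lambda r: (r.p, r.variant.id))
        loci: list[PqtlLocus] = []
        while remaining:
            index = remaining.pop(0)
            members = [index]
            keep = []
            for rec in remaining:
                same_chrom = rec.variant.chrom == index.variant.chrom
                close = abs(rec.variant.pos - index.variant.pos) <= merge_window_kb * 1000
                if same_chrom and close:
                    r2 = ld_r2(gm, index.variant.id, rec.variant.id)
                    if r2 is not None and r2 > merge_r2:
                        members.append(rec)
                        continue
                keep.append(rec)
            remaining = keep
            loci.append(PqtlLocus(index=index, members=members))
        out[trait] = loci
    return out


# ---------------------------------------------------------------------------
# cis / trans classification
# ---------------------------------------------------------------------------


def signed_distance_kb(pos: int, gene: GeneModel) -> float:
    """Signed distance from a position to a gene body in kb: 0 inside the
    gene, negative 5' of the gene (reference orientation), positive 3'."""
    if gene.start <= pos <= gene.end:
        return 0.0
    if pos < gene.start:
        return (pos - gene.start) / 1000.0
    return (pos - gene.end) / 1000.0


def classify_locus(locus: PqtlLocus, trait_gene: GeneModel,
                   cis_window_kb: float = 500.0, trans_min_mb: float = 100.0,
                   overrides: Sequence[str] = ()) -> PqtlLocus:
    """Assign cis/trans class and signed distance to a merged locus.

    cis: same chromosome and |distance| <= cis_window_kb, or the index
    variant id is named in ``overrides`` (the published analysis carried one
    such exception at 530.7 kb). trans: different chromosome (distance left
    absent) or distance >= trans_min_mb. Same-chromosome distances between
    the two bounds are classed "ambiguous".
    """
    v = locus.index.variant
    if v.chrom != trait_gene.chrom:
        locus.locus_class = "trans"
        locus.distance_kb = None
        return locus
    d = signed_distance_kb(v.pos, trait_gene)
    locus.distance_kb = d
    if abs(d) <= cis_window_kb or v.id in overrides:
        locus.locus_class = "cis"
    elif abs(d) >= trans_min_mb * 1000.0:
        locus.locus_class = "trans"
    else:
        import warnings

        warnings.warn(
            f"locus {v.id}: same-chromosome distance {d:.1f} kb falls between "
            f"the cis window and the trans minimum; classed ambiguous"
        )
        locus.locus_class = "ambiguous"
    return locus


def locus_table(loci_by_trait: dict[str, list[PqtlLocus]]) -> pd.DataFrame:
    """Headline locus table (trait, SNP, class, -log10 p)."""
    rows = []
    for trait, loci in loci_by_trait.items():
        for loc in loci:
            rows.append({
                "trait": trait,
                "id": loc.index.variant.id,
                "chrom": loc.index.variant.chrom,
                "pos": loc.index.variant.pos,
                "locus_class": loc.locus_class,
                "distance_kb": loc.distance_kb,
                "neg_log10_p": -math.log10(loc.index.p),
                "n_merged": len(loc.members),
            })
    return pd.DataFrame(rows)
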