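"""Synthetic cohorts with planted, recorded truth.

Every generator is a pure function of its specification and a seed, and
everything planted (pQTLs, eQTLs, mediator triples, disease-causal
proteins, censoring/noise settings) is recorded in a :class:`TruthTable`
so downstream stages can be tested by recovery.

The default cohort emulates the study conditions of the reference
protocol: 3,394 samples measured on a 92-assay panel of which 9 violate a
QC rule (83 survive), covariates age/sex/centre/batch/smoking/diabetes/
hypertension, planted cis effects (within 500 kb of the trait gene) and
trans effects (other chromosome), below-LOD censoring and inter-plate
noise, 11 expression datasets of n = 89-367 (mean 223), and a scale-free
interaction network with a planted cis-gene -> mediator -> trait-gene path
whose mediator carries a trans-eQTL of the index SNP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

from .datatypes import (
    EqtlDataset,
    GeneModel,
    GenotypeMatrix,
    ProteinPanel,
    ValidationError,
    Variant,
)
from .io import P_FLOOR


@dataclass
class TruthTable:
    """Everything planted by the generators, joinable to pipeline outputs."""

    pqtls: pd.DataFrame = field(default_factory=pd.DataFrame)
    eqtls: pd.DataFrame = field(default_factory=pd.DataFrame)
    mediators: pd.DataFrame = field(default_factory=pd.DataFrame)
    causal_proteins: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _normalize_variant_spec(variant_spec) -> list[dict]:
    out = []
    for k, entry in enumerate(variant_spec):
        if isinstance(entry, dict):
            d = dict(entry)
        else:
            chrom, pos, maf = entry
            d = {"chrom": chrom, "pos": pos, "maf": maf}
        d.setdefault("id", f"rs{k + 1}")
        d.setdefault("missense", False)
        if not (0 < d["maf"] <= 0.5):
            raise ValidationError(
                f"{d['id']}: maf must lie in (0, 0.5], got {d['maf']}")
        out.append(d)
    return out


def simulate_genotypes(n_samples: int, variant_spec, ld_rho: float,
                       seed: int) -> GenotypeMatrix:
    """Draw dosages as sums of two Bernoulli haplotypes.

    Within-chromosome LD comes from an order-1 autoregressive latent
    Gaussian with correlation ``ld_rho`` per haplotype, thresholded at each
    variant's minor-allele-frequency quantile, so pairwise dosage r² rises
    monotonically with ld_rho. ``variant_spec`` entries are (chrom, pos,
    maf) tuples or dicts with optional ``id``/``missense``/``block``; a
    ``block`` key restarts the AR chain, giving haplotype-block structure
    (LD within a block, independence across blocks).
    """
    if not (0 <= ld_rho < 1):
        raise ValidationError(f"ld_rho must lie in [0, 1), got {ld_rho}")
    spec = _normalize_variant_spec(variant_spec)
    rng = np.random.default_rng(seed)
    m = len(spec)
    dosage = np.empty((n_samples, m))
    # group columns by chromosome (and LD block, when given), preserving order
    by_chrom: dict[tuple, list[int]] = {}
    for j, d in enumerate(spec):
        key = (str(d["chrom"]), d.get("block"))
        by_chrom.setdefault(key, []).append(j)
    for cols in by_chrom.values():
        k = len(cols)
        thresholds = norm.ppf([spec[j]["maf"] for j in cols])
        for _hap in range(2):
            z = np.empty((n_samples, k))
            z[:, 0] = rng.standard_normal(n_samples)
            innov = rng.standard_normal((n_samples, k))
            for t in range(1, k):
                z[:, t] = ld_rho * z[:, t - 1] + math.sqrt(1 - ld_rho ** 2) * innov[:, t]
            alleles = (z < thresholds).astype(float)
            if _hap == 0:
                acc = alleles
            else:
                acc = acc + alleles
        dosage[:, cols] = acc
    samples = [f"S{i + 1}" for i in range(n_samples)]
    variants = [
        Variant(id=d["id"], chrom=str(d["chrom"]), pos=int(d["pos"]),
                coded_allele="A", other_allele="G",
                coded_freq=float(dosage[:, j].mean() / 2),
                missense=bool(d["missense"]))
        for j, d in enumerate(spec)
    ]
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


# ---------------------------------------------------------------------------
# protein panel
# ---------------------------------------------------------------------------


@dataclass
class CovariateSpec:
    """Clinical covariate structure of the simulated cohort."""

    n_centres: int = 7
    n_batches: int = 2
    plate_size: int = 88
    covariate_variance: float = 0.15  # protein variance explained by covariates


def _simulate_covariates(n: int, spec: CovariateSpec, rng) -> pd.DataFrame:
    return pd.DataFrame({
        "age": rng.normal(60.0, 8.0, n),
        "sex": rng.integers(0, 2, n),
        "centre": [f"C{c + 1}" for c in rng.integers(0, spec.n_centres, n)],
        "batch": [f"B{b + 1}" for b in rng.integers(0, spec.n_batches, n)],
        "smoking": rng.binomial(1, 0.25, n),
        "diabetes": rng.binomial(1, 0.20, n),
        "hypertension": rng.binomial(1, 0.50, n),
    })


def _plate_sd_for_cv(cv: float) -> float:
    """log10-scale plate-intercept sd giving (lognormal) inter-plate CV cv."""
    if cv <= 0:
        return 0.0
    sigma_ln = math.sqrt(math.log1p(cv * cv))
    return sigma_ln / math.log(10.0)


def simulate_protein_panel(
    gm: GenotypeMatrix,
    proteins: Sequence[str],
    effects: Sequence[tuple[str, str, float]],
    lod_censor_frac: Optional[dict[str, float]] = None,
    plate_cv: Optional[dict[str, float]] = None,
    seed: int = 0,
    covariates_spec: Optional[CovariateSpec] = None,
    noise_scale: float = 1.0,
) -> tuple[ProteinPanel, pd.DataFrame, TruthTable]:
    """Simulate a log10-scale protein panel with planted genetic effects.

    Each ``effects`` entry (variant_id, protein, variance_explained) adds a
    standardized dosage component scaled so it explains the stated variance
    fraction; covariates jointly explain ``covariates_spec.covariate_variance``;
    plate intercepts are random per plate with sd calibrated to the target
    inter-plate CV; the residual takes the remaining variance (times
    ``noise_scale``). Values below each assay's lod_censor_frac quantile
    are replaced by the LOD value; frac_below_lod and cv_interplate are
    recorded from the realized data (the CV from a pooled control measured
    once per plate).
    """
    cov_spec = covariates_spec or CovariateSpec()
    lod_censor_frac = lod_censor_frac or {}
    plate_cv = plate_cv or {}
    rng = np.random.default_rng(seed)
    n = gm.n_samples

    ve_by_protein: dict[str, float] = {}
    for vid, prot, ve in effects:
        if prot not in proteins:
            raise ValidationError(f"effect references unknown protein {prot!r}")
        gm.variant_index(vid)  # raises for unknown variant
        if not (0 < ve < 1):
            raise ValidationError(f"variance_explained must lie in (0,1): {ve}")
        ve_by_protein[prot] = ve_by_protein.get(prot, 0.0) + ve
    for prot, total in ve_by_protein.items():
        if total + cov_spec.covariate_variance >= 1:
            raise ValidationError(
                f"{prot}: variance budget {total + cov_spec.covariate_variance:.3f} >= 1")

    covariates = _simulate_covariates(n, cov_spec, rng)
    plates = [f"P{i // cov_spec.plate_size + 1}" for i in range(n)]
    plate_of = dict(zip(gm.samples, plates))
    plate_ids = sorted(set(plates))
    plate_index = np.array([plate_ids.index(p) for p in plates])

    # numeric covariate design for the planted covariate component
    age_z = (covariates["age"] - covariates["age"].mean()) / covariates["age"].std()
    num_cols = [age_z.to_numpy(),
                covariates["sex"].to_numpy(float),
                covariates["smoking"].to_numpy(float),
                covariates["diabetes"].to_numpy(float),
                covariates["hypertension"].to_numpy(float)]
    centre_d = pd.get_dummies(covariates["centre"], dtype=float).to_numpy()
    batch_d = pd.get_dummies(covariates["batch"], dtype=float).to_numpy()
    Xc = np.column_stack(num_cols + [centre_d, batch_d])

    values = np.empty((n, len(proteins)))
    truth_rows = []
    frac_below: dict[str, float] = {}
    cv_real: dict[str, float] = {}
    for k, prot in enumerate(proteins):
        baseline = rng.normal(1.0, 0.3)
        y = np.full(n, baseline)
        total_ve = 0.0
        for vid, eprot, ve in effects:
            if eprot != prot:
                continue
            g = gm.column(vid)
            sd = g.std()
            if sd == 0:
                raise ValidationError(f"{vid}: monomorphic effect variant")
            y = y + math.sqrt(ve) * (g - g.mean()) / sd
            total_ve += ve
            truth_rows.append({
                "id": vid, "protein": prot,
                "beta": math.sqrt(ve) / sd, "variance_explained": ve,
            })
        cov_var = cov_spec.covariate_variance
        if cov_var > 0:
            w = rng.normal(0.0, 1.0, Xc.shape[1])
            c_raw = Xc @ w
            c_sd = c_raw.std()
            if c_sd > 0:
                y = y + math.sqrt(cov_var) * (c_raw - c_raw.mean()) / c_sd
        s_plate = _plate_sd_for_cv(plate_cv.get(prot, 0.0))
        plate_eff = rng.normal(0.0, s_plate, len(plate_ids)) if s_plate else None
        if plate_eff is not None:
            y = y + plate_eff[plate_index]
        resid_var = max(1.0 - total_ve - cov_var, 0.0)
        y = y + noise_scale * math.sqrt(resid_var) * rng.standard_normal(n)
        if y.std() == 0:
            raise ValidationError(f"{prot}: generated column is constant")
        # below-LOD censoring: the lowest lod_censor_frac of values sit at LOD
        frac = lod_censor_frac.get(prot, 0.0)
        if frac > 0:
            lod = np.quantile(y, frac)
            censored = y < lod
            y = np.where(censored, lod, y)
            frac_below[prot] = float(censored.mean())
        else:
            frac_below[prot] = 0.0
        # pooled control measured once per plate -> inter-plate CV (linear scale)
        control = 1.0 + (plate_eff if plate_eff is not None
                         else np.zeros(len(plate_ids)))
        control = control + rng.normal(0.0, 0.004, len(plate_ids))
        lin = np.power(10.0, control)
        cv_real[prot] = float(lin.std(ddof=1) / lin.mean())
        values[:, k] = y

    panel = ProteinPanel(samples=list(gm.samples), proteins=list(proteins),
                         values=values, frac_below_lod=frac_below,
                         cv_interplate=cv_real, plate_of=plate_of)
    covariates.index = pd.Index(gm.samples)
    vmeta = {v.id: v for v in gm.variants}
    pqtls = pd.DataFrame(truth_rows)
    if not pqtls.empty:
        pqtls["chrom"] = [vmeta[i].chrom for i in pqtls["id"]]
        pqtls["pos"] = [vmeta[i].pos for i in pqtls["id"]]
        pqtls["coded_allele"] = [vmeta[i].coded_allele for i in pqtls["id"]]
        pqtls["other_allele"] = [vmeta[i].other_allele for i in pqtls["id"]]
    truth = TruthTable(pqtls=pqtls,
                       params={"seed": seed, "noise_scale": noise_scale,
                               "covariate_variance": cov_spec.covariate_variance,
                               "lod_censor_frac": dict(lod_censor_frac),
                               "plate_cv": dict(plate_cv)})
    return panel, covariates, truth


# ---------------------------------------------------------------------------
# expression datasets
# ---------------------------------------------------------------------------


def simulate_expression(gm: GenotypeMatrix, genes: Sequence[str],
                        eqtl_spec: Sequence[tuple[str, str, Optional[str], float]],
                        dataset_sizes: dict[str, int], seed: int
                        ) -> tuple[list[EqtlDataset], TruthTable]:
    """Simulate log2 expression datasets with planted additive eQTLs.

    ``eqtl_spec`` entries are (variant_id, gene, dataset or None for all
    datasets, variance_explained). Subjects are subsampled independently
    per dataset and noise is independent across datasets.
    """
    genes = list(genes)
    for vid, gene, ds_name, ve in eqtl_spec:
        gm.variant_index(vid)
        if gene not in genes:
            raise ValidationError(f"eqtl references unknown gene {gene!r}")
        if ds_name is not None and ds_name not in dataset_sizes:
            raise ValidationError(f"eqtl references unknown dataset {ds_name!r}")
        if not (0 < ve < 1):
            raise ValidationError(f"variance_explained must lie in (0,1): {ve}")
    for name, size in dataset_sizes.items():
        if size < 30:
            raise ValidationError(f"dataset {name!r}: n = {size} < 30")
        if size > gm.n_samples:
            raise ValidationError(f"dataset {name!r}: n exceeds cohort size")

    rng = np.random.default_rng(seed)
    datasets = []
    truth_rows = []
    for name in dataset_sizes:
        size = dataset_sizes[name]
        pick = np.sort(rng.choice(gm.n_samples, size=size, replace=False))
        sub = gm.subset_samples(pick)
        expr = np.empty((size, len(genes)))
        for j, gene in enumerate(genes):
            baseline = rng.normal(8.0, 1.0)
            y = np.full(size, baseline)
            total_ve = 0.0
            for vid, egene, ds_name, ve in eqtl_spec:
                if egene != gene or (ds_name is not None and ds_name != name):
                    continue
                g = sub.column(vid)
                sd = g.std()
                if sd == 0:
                    continue  # variant monomorphic in this subsample
                y = y + math.sqrt(ve) * (g - g.mean()) / sd
                total_ve += ve
                truth_rows.append({"id": vid, "gene": gene, "dataset": name,
                                   "variance_explained": ve,
                                   "beta": math.sqrt(ve) / sd})
            y = y + math.sqrt(max(1.0 - total_ve, 1e-12)) * rng.standard_normal(size)
            expr[:, j] = y
        datasets.append(EqtlDataset(
            name=name,
            expression=pd.DataFrame(expr, index=sub.samples, columns=genes),
            genotypes=sub,
        ))
    truth = TruthTable(eqtls=pd.DataFrame(truth_rows),
                       params={"seed": seed,
                               "dataset_sizes": dict(dataset_sizes)})
    return datasets, truth


#: 11 expression dataset sizes (n 89-367, mean exactly 223)
DEFAULT_EQTL_SIZES = {
    "aorta_media": 89, "aorta_adventitia": 120, "liver": 150,
    "mammary_artery": 180, "heart": 200, "monocytes": 223, "b_cells": 240,
    "monocytes_lps2": 260, "monocytes_lps24": 290, "monocytes_ifn": 334,
    "whole_blood": 367,
}


# ---------------------------------------------------------------------------
# interaction network
# ---------------------------------------------------------------------------


def simulate_network(genes: Sequence[str], m_attach: int,
                     planted_edges: Sequence[tuple[str, str, int]],
                     seed: int, net_min_conf: int = 400) -> nx.Graph:
    """Scale-free gene network by preferential attachment, plus planted edges.

    Each new node attaches to ``m_attach`` existing nodes with probability
    proportional to degree; random confidences are uniform in [401, 1000];
    planted edges are added (or their confidence overwritten) afterwards.
    """
    genes = list(genes)
    if m_attach < 1:
        raise ValidationError("m_attach must be >= 1")
    if len(genes) <= m_attach:
        raise ValidationError("need more genes than m_attach")
    for a, b, conf in planted_edges:
        if a not in genes or b not in genes:
            missing = a if a not in genes else b
            raise ValidationError(f"planted edge references unknown gene {missing!r}")
        if conf <= net_min_conf:
            raise ValidationError(
                f"planted confidence {conf} must exceed {net_min_conf}")
    rng = np.random.default_rng(seed)
    base = nx.barabasi_albert_graph(len(genes), m_attach,
                                    seed=int(rng.integers(2 ** 31)))
    g = nx.relabel_nodes(base, {i: genes[i] for i in range(len(genes))})
    confs = rng.integers(401, 1001, size=g.number_of_edges())
    for k, (a, b) in enumerate(sorted(g.edges())):
        g[a][b]["confidence"] = int(confs[k])
    for a, b, conf in planted_edges:
        g.add_edge(a, b, confidence=int(conf))
    return g


# ---------------------------------------------------------------------------
# disease summary statistics
# ---------------------------------------------------------------------------


def simulate_disease_sumstats(pqtl_truth: TruthTable,
                              causal_proteins: Sequence[str],
                              se_scale: float, seed: int,
                              proportionality: float = 0.5,
                              null_variants: Sequence[Variant] = (),
                              trait: str = "CAD") -> pd.DataFrame:
    """Disease GWAS summary statistics over the planted pQTL variants.

    Variants of causal proteins get a disease beta proportional to the
    protein beta (shared direction) plus N(0, se) sampling noise; all other
    variants (and any extra ``null_variants``) are drawn from the null.
    The se is constant = se_scale and p is the two-sided normal tail.
    """
    known = set(pqtl_truth.pqtls["protein"]) if not pqtl_truth.pqtls.empty else set()
    for prot in causal_proteins:
        if prot not in known:
            raise ValidationError(f"unknown causal protein {prot!r}")
    if se_scale <= 0:
        raise ValidationError("se_scale must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for _, r in pqtl_truth.pqtls.iterrows():
        causal = r["protein"] in causal_proteins
        mean = proportionality * r["beta"] if causal else 0.0
        beta = mean + rng.normal(0.0, se_scale)
        p = max(2.0 * float(norm.sf(abs(beta / se_scale))), P_FLOOR)
        rows.append({
            "id": r["id"], "chrom": r.get("chrom", "NA"),
            "pos": r.get("pos", 1),
            "coded_allele": r.get("coded_allele", "A"),
            "other_allele": r.get("other_allele", "G"),
            "trait": trait, "beta": beta, "se": se_scale, "p": p, "n": 184_000,
        })
    for v in null_variants:
        beta = rng.normal(0.0, se_scale)
        p = max(2.0 * float(norm.sf(abs(beta / se_scale))), P_FLOOR)
        rows.append({"id": v.id, "chrom": v.chrom, "pos": v.pos,
                     "coded_allele": v.coded_allele,
                     "other_allele": v.other_allele,
                     "trait": trait, "beta": beta, "se": se_scale, "p": p,
                     "n": 184_000})
    df = pd.DataFrame(rows).drop_duplicates(subset="id", keep="first")
    return df.reset_index(drop=True)
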