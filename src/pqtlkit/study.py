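"""The default synthetic study: one bundle of cohort, annotation, expression
datasets, network and disease statistics with recorded truth.

These settings are the package's standing study conditions, emulating the
reference protocol at its published sizes: a discovery cohort of 3,394
samples, a 92-assay panel of which 9 violate a QC rule (83 survive),
age/sex/centre/batch/smoking/diabetes/hypertension covariates, planted cis
effects (SNP within the trait gene) and trans effects (trait gene on
another chromosome), 11 expression datasets of n = 89-367, a scale-free
200-gene interaction network carrying a planted
cis-gene -> mediator -> trait-gene path whose mediator is a trans-eQTL
target of the index SNP, and a disease GWAS in which two proteins are
causal. Only the seed varies between runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .datatypes import EqtlDataset, GeneModel, GenotypeMatrix, ProteinPanel
from .simulate import (
    DEFAULT_EQTL_SIZES,
    TruthTable,
    simulate_disease_sumstats,
    simulate_expression,
    simulate_genotypes,
    simulate_network,
    simulate_protein_panel,
)

N_SAMPLES = 3394
N_ASSAYS = 92
#: latent AR correlation inside an LD block; adjacent dosage r² ~ 0.5
LD_RHO = 0.8

#: 13 haplotype blocks of 3 variants per chromosome; 50 kb spacing inside
#: a block, 300 kb between block starts (blocks are LD-independent)
BLOCKS_PER_CHROM = 13
BLOCK_SIZE = 3
VARIANTS_PER_CHROM = BLOCKS_PER_CHROM * BLOCK_SIZE
CHROMS = ("1", "9", "19")

#: planted cis pQTLs (protein, chr1 variant index, variance explained);
#: every effect sits mid-block, so its block-mates merge into the locus;
#: every effect is >= 2% of protein variance
CIS_EFFECTS = [
    ("PROT01", 1, 0.02),
    ("PROT02", 7, 0.03),
    ("PROT03", 13, 0.05),
    ("PROT04", 19, 0.05),
    ("PROT05", 25, 0.08),
    ("PROT06", 31, 0.10),
]

#: planted trans pQTLs (protein, chr9 variant index, variance explained);
#: trait genes sit on chromosome 2, so every effect is cross-chromosome
TRANS_EFFECTS = [
    ("PROT07", 1, 0.05),
    ("PROT08", 10, 0.03),
    ("PROT09", 19, 0.02),
    ("PROT10", 28, 0.08),
]

#: the mediated trans locus: chr9 variant 1 -> CISG1 (overlapping cis-gene)
#: -> MED1 -> PROT07 (trait gene); MED1 carries a trans-eQTL of the SNP
MEDIATOR_TRIPLE = ("CISG1", "MED1", "PROT07")

#: assays violating QC: 6 by below-LOD fraction, 3 by inter-plate CV
LOD_VIOLATORS = ["PROT87", "PROT88", "PROT89", "PROT90", "PROT91", "PROT92"]
CV_VIOLATORS = ["PROT84", "PROT85", "PROT86"]
#: violator targets sit far from the QC cutoffs so sampling noise in the
#: realized metadata cannot blur the planted violation
LOD_TARGET, CV_TARGET = 0.25, 0.50

CAUSAL_PROTEINS = ["PROT05", "PROT07"]
DISEASE_SE = 0.01

N_NETWORK_GENES = 200
M_ATTACH = 2


def variant_grid() -> list[dict]:
    spec = []
    k = 0
    for chrom in CHROMS:
        for i in range(VARIANTS_PER_CHROM):
            k += 1
            block, offset = divmod(i, BLOCK_SIZE)
            spec.append({
                "id": f"rs{k}", "chrom": chrom, "block": block,
                "pos": 1_000_000 + 300_000 * block + 50_000 * offset,
                # variants sharing a haplotype block share an allele
                # frequency, as high pairwise LD requires
                "maf": 0.10 + 0.04 * (block % 10),
            })
    return spec


def _variant_id(chrom: str, index: int) -> str:
    base = CHROMS.index(chrom) * VARIANTS_PER_CHROM
    return f"rs{base + index + 1}"


def gene_annotation() -> list[GeneModel]:
    """Trait genes for all 92 proteins plus the candidate cis-genes of the
    mediated trans locus."""
    genes: list[GeneModel] = []
    spec = {d["id"]: d for d in variant_grid()}
    # cis proteins: gene bodies overlapping their effect SNP on chr 1
    for prot, vidx, _ in CIS_EFFECTS:
        pos = spec[_variant_id("1", vidx)]["pos"]
        genes.append(GeneModel(prot, prot, "1", pos - 20_000, pos + 30_000))
    # all other trait genes live on chromosome 2 (no variants there)
    others = [f"PROT{k:02d}" for k in range(1, N_ASSAYS + 1)
              if f"PROT{k:02d}" not in {c[0] for c in CIS_EFFECTS}]
    for k, prot in enumerate(others):
        start = 1_000_000 + 2_000_000 * k
        genes.append(GeneModel(prot, prot, "2", start, start + 50_000))
    # candidate cis-genes around the mediated trans SNP (chr9, mid-block 0)
    pos = spec[_variant_id("9", 1)]["pos"]
    genes.append(GeneModel("CISG1", "CISG1", "9", pos - 10_000, pos + 40_000))
    genes.append(GeneModel("CISG2", "CISG2", "9", pos + 150_000, pos + 190_000))
    genes.append(GeneModel("CISG3", "CISG3", "9", pos - 330_000, pos - 300_000))
    return genes


def network_genes() -> list[str]:
    trait_genes = [f"PROT{k:02d}" for k in range(1, N_ASSAYS + 1)]
    extra = ["CISG1", "CISG2", "CISG3", "MED1"]
    filler = [f"NG{k:03d}" for k in range(1, N_NETWORK_GENES
                                          - len(trait_genes) - len(extra) + 1)]
    return trait_genes + extra + filler


@dataclass
class SyntheticStudy:
    genotypes: GenotypeMatrix
    panel: ProteinPanel
    covariates: pd.DataFrame
    annotation: list[GeneModel]
    truth: TruthTable
    eqtl_datasets: list[EqtlDataset] = field(default_factory=list)
    network: nx.Graph | None = None
    disease_sumstats: pd.DataFrame | None = None

    @property
    def trait_gene_of(self) -> dict[str, str]:
        # trait-gene symbol equals the protein name in this study
        return {p: p for p in self.panel.proteins}


def default_study(seed: int, with_expression: bool = True,
                  with_network: bool = True,
                  with_disease: bool = True) -> SyntheticStudy:
    """Build the full default study for one seed.

    The expression/network/disease layers can be switched off for runs
    that only exercise the discovery scan.
    """
    gm = simulate_genotypes(N_SAMPLES, variant_grid(), LD_RHO, seed=seed)
    proteins = [f"PROT{k:02d}" for k in range(1, N_ASSAYS + 1)]
    effects = [(_variant_id("1", vidx), prot, ve)
               for prot, vidx, ve in CIS_EFFECTS]
    effects += [(_variant_id("9", vidx), prot, ve)
                for prot, vidx, ve in TRANS_EFFECTS]
    lod = {p: 0.02 for p in proteins}
    lod.update({p: LOD_TARGET for p in LOD_VIOLATORS})
    cv = {p: 0.05 for p in proteins}
    cv.update({p: CV_TARGET for p in CV_VIOLATORS})
    panel, covariates, truth = simulate_protein_panel(
        gm, proteins, effects, lod_censor_frac=lod, plate_cv=cv,
        seed=seed + 1)
    # record planted locus classes: cis SNPs sit inside their trait gene
    cls = {}
    for prot, vidx, _ in CIS_EFFECTS:
        cls[(_variant_id("1", vidx), prot)] = "cis"
    for prot, vidx, _ in TRANS_EFFECTS:
        cls[(_variant_id("9", vidx), prot)] = "trans"
    if not truth.pqtls.empty:
        truth.pqtls["cls"] = [cls[(r["id"], r["protein"])]
                              for _, r in truth.pqtls.iterrows()]
    truth.causal_proteins = list(CAUSAL_PROTEINS)
    cis_gene, mediator, trait_gene = MEDIATOR_TRIPLE
    snp_id = _variant_id("9", 1)
    truth.mediators = pd.DataFrame([{
        "id": snp_id, "cis_gene": cis_gene, "mediator": mediator,
        "trait_gene": trait_gene,
    }])

    study = SyntheticStudy(genotypes=gm, panel=panel, covariates=covariates,
                           annotation=gene_annotation(), truth=truth)

    if with_expression:
        genes = network_genes()
        eqtl_spec = [
            # the mediator is a trans-eQTL target of the index SNP everywhere
            (snp_id, mediator, None, 0.10),
            # the overlapping cis-gene shows a strong cis-eQTL
            (snp_id, cis_gene, None, 0.25),
        ]
        datasets, eqtl_truth = simulate_expression(
            gm, genes, eqtl_spec, DEFAULT_EQTL_SIZES, seed=seed + 2)
        study.eqtl_datasets = datasets
        truth.eqtls = eqtl_truth.eqtls

    if with_network:
        planted = [(cis_gene, mediator, 900), (mediator, trait_gene, 900)]
        net = simulate_network(network_genes(), M_ATTACH, planted,
                               seed=seed + 3)
        # the mediated route must be the shortest: drop an accidental
        # direct cis-gene/trait-gene edge if preferential attachment made one
        if net.has_edge(cis_gene, trait_gene):
            net.remove_edge(cis_gene, trait_gene)
        study.network = net

    if with_disease:
        study.disease_sumstats = simulate_disease_sumstats(
            truth, CAUSAL_PROTEINS, DISEASE_SE, seed=seed + 4)

    return study
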