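"""High-level pipeline steps over a study bundle.

Thin orchestration only: each function chains the module-level operations
in protocol order (QC -> residualize -> scan -> merge -> classify;
disease lookup -> harmonize -> pool -> FDR).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .assoc import (
    classify_locus,
    merge_loci,
    qc_genotypes,
    qc_proteins,
    residualize,
    wald_scan,
)
from .config import RunConfig
from .datatypes import GeneModel, PqtlLocus
from .downstream import (
    RiskScoreResult,
    flag_risk_scores,
    harmonize_to_risk,
    pooled_score,
)
from .study import SyntheticStudy


@dataclass
class DiscoveryResult:
    loci_by_trait: dict[str, list[PqtlLocus]]
    n_assays_retained: int
    n_variants_retained: int
    n_flagged: int = 0
    all_records: list = field(default_factory=list)

    @property
    def loci(self) -> list[tuple[str, PqtlLocus]]:
        return [(t, loc) for t, ll in self.loci_by_trait.items() for loc in ll]


def discover_loci(study: SyntheticStudy, cfg: Optional[RunConfig] = None,
                  keep_records: bool = False) -> DiscoveryResult:
    """QC both matrices, residualize, scan, merge and classify."""
    cfg = cfg or RunConfig()
    panel, _ = qc_proteins(study.panel, cfg.lod_frac, cfg.cv_max)
    gm, _ = qc_genotypes(study.genotypes, cfg.hwe_p, cfg.call_rate)
    resid = residualize(panel, study.covariates)
    records, flagged = wald_scan(resid, gm, cfg.p_gw)
    loci_by_trait = merge_loci(flagged, cfg.merge_r2, cfg.merge_window_kb, gm)
    gene_of = {g.symbol: g for g in study.annotation}
    for trait, loci in loci_by_trait.items():
        trait_gene = gene_of.get(study.trait_gene_of.get(trait, trait))
        if trait_gene is None:
            raise KeyError(f"no gene model for trait {trait!r}")
        for locus in loci:
            classify_locus(locus, trait_gene, cfg.cis_window_kb,
                           cfg.trans_min_mb)
    return DiscoveryResult(
        loci_by_trait=loci_by_trait,
        n_assays_retained=len(panel.proteins),
        n_variants_retained=gm.n_variants,
        n_flagged=len(flagged),
        all_records=records if keep_records else [],
    )


def disease_risk_scores(result: DiscoveryResult,
                        disease_sumstats: pd.DataFrame,
                        q: float = 0.05) -> list[RiskScoreResult]:
    """Per-protein pooled disease scores over discovered index SNPs,
    FDR-flagged as one family."""
    by_id = {r["id"]: r for _, r in disease_sumstats.iterrows()}
    results = []
    for trait, loci in result.loci_by_trait.items():
        aligned = []
        for locus in loci:
            v = locus.index.variant
            row = by_id.get(v.id)
            if row is None:
                continue
            rec = harmonize_to_risk(
                {"id": v.id, "coded_allele": v.coded_allele,
                 "other_allele": v.other_allele},
                dict(row))
            if rec is not None:
                aligned.append(rec)
        if aligned:
            results.append(pooled_score(trait, aligned))
    return flag_risk_scores(results, q=q)


def permutation_null_calibration(seed: int, n_graphs: int = 5,
                                 pairs_per_graph: int = 100,
                                 n_perm: int = 200, n_nodes: int = 120,
                                 mean_degree: float = 3.0,
                                 alpha: float = 0.05) -> float:
    """Empirical false-positive rate of the path permutation test on null
    (Erdos-Renyi) graphs.

    Draws ``n_graphs`` independent ER graphs, samples non-adjacent
    connected source-target pairs from each (pairs with no short, i.e.
    direct, connection), computes each pair's permutation p and returns
    the fraction below ``alpha``. The rewired-network null draws are
    shared across a graph's pairs (see path_permutation_null).
    """
    import networkx as nx
    import numpy as np

    from .mediators import path_permutation_null

    ps: list[float] = []
    for k in range(n_graphs):
        gseed = seed * 1000 + k
        g0 = nx.gnp_random_graph(n_nodes, mean_degree / (n_nodes - 1),
                                 seed=gseed)
        g = nx.Graph()
        g.add_nodes_from(str(i) for i in g0.nodes)
        for a, b in g0.edges():
            g.add_edge(str(a), str(b), confidence=800)
        rng = np.random.default_rng(gseed + 100)
        nodes = sorted(g.nodes)
        pairs: list[tuple[str, str]] = []
        tries = 0
        while len(pairs) < pairs_per_graph and tries < 100 * pairs_per_graph:
            tries += 1
            s, t = rng.choice(nodes, 2, replace=False)
            if g.has_edge(s, t) or not nx.has_path(g, s, t):
                continue
            pairs.append((s, t))
        ps.extend(p for p in path_permutation_null(g, None, pairs, n_perm,
                                                   gseed + 200)
                  if p is not None)
    return float(np.mean([p < alpha for p in ps]))


def recovery_report(study: SyntheticStudy, result: DiscoveryResult) -> dict:
    """Join discovered loci to the planted truth.

    A planted pQTL counts as recovered when a locus for its protein
    contains the planted variant among its members; it is correctly
    classified when the locus class matches the planted class. Any locus
    whose members contain no planted variant for that protein is a false
    discovery.
    """
    truth = study.truth.pqtls
    planted = {(r["id"], r["protein"]): r.get("cls")
               for _, r in truth.iterrows()}
    recovered = {}
    false_loci = []
    for trait, locus in result.loci:
        member_ids = {m.variant.id for m in locus.members}
        hit = [key for key in planted
               if key[1] == trait and key[0] in member_ids]
        if hit:
            recovered[hit[0]] = locus.locus_class
        else:
            false_loci.append((trait, locus.index.variant.id))
    n_correct = sum(1 for key, cls in recovered.items()
                    if planted[key] == cls)
    return {
        "n_planted": len(planted),
        "n_recovered": len(recovered),
        "n_correctly_classified": n_correct,
        "false_loci": false_loci,
    }
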