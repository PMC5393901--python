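"""Evidence tracks for trans-pQTL mediator genes.

For each trans locus, every gene within the cis window of the index SNP is
a candidate mediator and is scored on five tracks:

1. a missense coding proxy in LD (r² > 0.6) with the index SNP;
2. a cis-eQTL of the index SNP on the candidate (p < 5e-4, FDR < 5%);
3. an unweighted shortest path to the trait gene in the interaction
   network shorter than in 95% of degree-preserving rewired networks;
4. the same test with each step weighted by the trans-eQTL strength of the
   entered gene (score 1, or 0.8 if best eQTL p < 0.05, or 0.6 if
   p < 0.005) — this lets a strong trans-eQTL intermediary make a two-hop
   path significant where hop count alone cannot;
5. a literature co-occurrence score above 50.

The permutation null rewires the network by double-edge swaps (degree
sequence preserved exactly) and independently permutes the node scores;
the p-value is the fraction of permuted networks with a strictly shorter
path, disconnections counting as not-shorter.
"""

from __future__ import annotations

import heapq
import logging
from math import inf
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .config import RunConfig
from .datatypes import (
    EqtlDataset,
    EvidenceRow,
    GeneModel,
    GenotypeMatrix,
    NodeScoreMap,
    PathResult,
    PqtlLocus,
    Variant,
)
from .assoc import signed_distance_kb

logger = logging.getLogger(__name__)


class NodeAbsentError(KeyError):
    """Source or target gene is not a node of the network (distinct from a
    disconnected but present pair)."""


# ---------------------------------------------------------------------------
# candidate enumeration and per-candidate evidence
# ---------------------------------------------------------------------------


def enumerate_cis_genes(snp: Variant, annotation: Sequence[GeneModel],
                        window_kb: float = 500.0
                        ) -> list[tuple[GeneModel, float, int]]:
    """All genes whose body lies within window_kb of the SNP, with signed
    distance (0 when overlapping) and 1-based rank by |distance| (ties by
    gene start)."""
    hits = []
    for g in annotation:
        if g.chrom != snp.chrom:
            continue
        d = signed_distance_kb(snp.pos, g)
        if abs(d) <= window_kb:
            hits.append((g, d))
    hits.sort(key=lambda t: (abs(t[1]), t[0].start, t[0].gene_id))
    return [(g, d, rank) for rank, (g, d) in enumerate(hits, start=1)]


def coding_proxy_evidence(snp: Variant, variants: Sequence[Variant],
                          ld_ref: GenotypeMatrix, coding_r2: float = 0.6,
                          window_kb: float = 500.0
                          ) -> Optional[tuple[Variant, float]]:
    """Best missense variant in LD with the index SNP (r² > coding_r2,
    within ±window_kb); the index SNP itself qualifies at r² = 1 when it is
    missense."""
    from .assoc import ld_r2

    best: Optional[tuple[Variant, float]] = None
    for v in variants:
        if not v.missense or v.chrom != snp.chrom:
            continue
        if abs(v.pos - snp.pos) > window_kb * 1000:
            continue
        r2 = 1.0 if v.id == snp.id else ld_r2(ld_ref, snp.id, v.id)
        if r2 is None or r2 <= coding_r2:
            continue
        if best is None or r2 > best[1]:
            best = (v, r2)
    return best


def _regression_p(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    """Two-sided p for the slope of y on x (t law, n-2 df); None when
    degenerate."""
    mask = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        return None
    sxx = ((x - x.mean()) ** 2).sum()
    syy = ((y - y.mean()) ** 2).sum()
    if sxx == 0 or syy == 0:
        return None
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    beta = sxy / sxx
    rss = max(syy - beta * sxy, 0.0)
    if rss == 0:
        return float(np.finfo(float).tiny)
    se = np.sqrt(rss / (n - 2) / sxx)
    return 2.0 * float(stats.t.sf(abs(beta / se), n - 2))


def cis_eqtl_scan(snp: Variant, gene: str, datasets: Sequence[EqtlDataset],
                  eqtl_cis_p: float = 5e-4) -> list[tuple[str, float]]:
    """Per-dataset simple-regression p of log2 expression on dosage;
    datasets with p < eqtl_cis_p (strict) are reported with uncorrected p.
    Datasets lacking the gene or the SNP are skipped."""
    hits = []
    for ds in datasets:
        if gene not in ds.expression.columns:
            logger.debug("cis_eqtl_scan: %s lacks gene %s", ds.name, gene)
            continue
        try:
            g = ds.genotypes.column(snp.id)
        except KeyError:
            logger.debug("cis_eqtl_scan: %s lacks variant %s", ds.name, snp.id)
            continue
        p = _regression_p(g, ds.expression[gene].to_numpy())
        if p is not None and p < eqtl_cis_p:
            hits.append((ds.name, p))
    return hits


def trans_eqtl_scores(snp: Variant, datasets: Sequence[EqtlDataset],
                      network_genes: Iterable[str],
                      w1_p: float = 0.05, w2_p: float = 0.005) -> NodeScoreMap:
    """Score every network gene by its best (minimum) eQTL p of the index
    SNP across datasets: 0.6 below w2_p, 0.8 below w1_p, else 1. Genes
    never measured score 1."""
    best: dict[str, tuple[float, str]] = {}
    for ds in datasets:
        try:
            g = ds.genotypes.column(snp.id)
        except KeyError:
            continue
        for gene in ds.expression.columns:
            p = _regression_p(g, ds.expression[gene].to_numpy())
            if p is None:
                continue
            if gene not in best or p < best[gene][0]:
                best[gene] = (p, ds.name)
    scores: dict[str, float] = {}
    provenance: dict[str, tuple[float, str]] = {}
    for gene in network_genes:
        if gene in best:
            p, ds_name = best[gene]
            provenance[gene] = (p, ds_name)
            scores[gene] = 0.6 if p < w2_p else 0.8 if p < w1_p else 1.0
        else:
            scores[gene] = 1.0
    return NodeScoreMap(scores=scores, provenance=provenance)


# ---------------------------------------------------------------------------
# shortest paths
# ---------------------------------------------------------------------------


def _weighted_shortest(adj: dict, source: str, target: str,
                       score) -> tuple[float, list[str]]:
    """Dijkstra where traversing an edge into node v costs score(v);
    the source's own score is not counted. Ties broken by node order."""
    dist = {source: 0.0}
    prev: dict[str, str] = {}
    heap: list[tuple[float, str]] = [(0.0, source)]
    done = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        if u == target:
            break
        for v in adj[u]:
            nd = d + score(v)
            if v not in dist or nd < dist[v] - 1e-15:
                dist[v] = nd
                prev[v] = u
                heapq.heappush(heap, (nd, v))
    if target not in done:
        return inf, []
    path = [target]
    while path[-1] != source:
        path.append(prev[path[-1]])
    return dist[target], path[::-1]


def shortest_path(network: nx.Graph, source: str, target: str,
                  scores: Optional[NodeScoreMap] = None) -> PathResult:
    """Unweighted (minimum edge count) and, when scores are given,
    node-score-weighted shortest paths between two genes.

    The weighted length of a path is the sum of the scores of every node
    entered along it (source excluded), so with all scores 1 the two
    lengths coincide. Both are inf when the pair is disconnected; a missing
    node raises NodeAbsentError.
    """
    if source not in network:
        raise NodeAbsentError(f"source gene {source!r} not in network")
    if target not in network:
        raise NodeAbsentError(f"target gene {target!r} not in network")
    if source == target:
        raise ValueError("source and target must differ")
    try:
        nodes = nx.shortest_path(network, source, target)
        unweighted = float(len(nodes) - 1)
    except nx.NetworkXNoPath:
        nodes, unweighted = [], inf
    if scores is None:
        weighted, wnodes = unweighted, list(nodes)
    else:
        adj = {u: sorted(network[u]) for u in network}
        weighted, wnodes = _weighted_shortest(adj, source, target, scores.score)
    return PathResult(source=source, target=target, nodes=list(nodes),
                      unweighted_len=unweighted, weighted_len=weighted,
                      weighted_nodes=wnodes)


# ---------------------------------------------------------------------------
# rewiring null
# ---------------------------------------------------------------------------


def rewire_network(network: nx.Graph, seed, n_attempts: Optional[int] = None
                   ) -> nx.Graph:
    """Degree-preserving randomization by double-edge swaps.

    Two edges (a,b), (c,d) are replaced by (a,d), (c,b) when that creates
    neither a self-loop nor a multi-edge. 10·|E| swaps are attempted (the
    standard burn-in for configuration-model mixing); edge confidences are
    carried by edge slot. Deterministic given the seed. Networks with fewer
    than 2 edges are returned unchanged (as a copy).
    """
    edges = [(a, b, d.get("confidence", 1000)) for a, b, d in
             network.edges(data=True)]
    m = len(edges)
    if m < 2:
        return network.copy()
    if n_attempts is None:
        n_attempts = 10 * m
    rng = np.random.default_rng(seed)
    present = {frozenset((a, b)) for a, b, _ in edges}
    idx = rng.integers(0, m, size=2 * n_attempts)
    flip = rng.integers(0, 2, size=n_attempts)
    for t in range(n_attempts):
        i, j = int(idx[2 * t]), int(idx[2 * t + 1])
        if i == j:
            continue
        a, b, ci = edges[i]
        c, d, cj = edges[j]
        if flip[t]:
            c, d = d, c
        # proposed: (a, d) and (c, b)
        if a == d or c == b:
            continue
        e1, e2 = frozenset((a, d)), frozenset((c, b))
        if e1 == e2 or e1 in present or e2 in present:
            continue
        present.discard(frozenset((a, b)))
        present.discard(frozenset((c, d)))
        present.add(e1)
        present.add(e2)
        edges[i] = (a, d, ci)
        edges[j] = (c, b, cj)
    out = nx.Graph()
    out.add_nodes_from(network.nodes)
    for a, b, conf in edges:
        out.add_edge(a, b, confidence=conf)
    return out


def _permute_scores(scores: NodeScoreMap, nodes: Sequence[str], seed
                    ) -> NodeScoreMap:
    rng = np.random.default_rng(seed)
    vals = np.array([scores.score(n) for n in nodes])
    perm = rng.permutation(len(nodes))
    return NodeScoreMap(scores={n: float(vals[perm[k]])
                                for k, n in enumerate(nodes)})


def _perm_seeds(seed: int, b: int) -> tuple[list[int], list[int]]:
    # independent streams for rewiring and score permutation of replicate b
    return [int(seed) + b, 1], [int(seed) + b, 2]


def path_permutation_p(network: nx.Graph, scores: Optional[NodeScoreMap],
                       source: str, target: str, n_perm: int = 1000,
                       seed: int = 0, weighted: bool = False,
                       estimator: str = "plain") -> float:
    """Permutation significance of an observed shortest path.

    For each of n_perm replicates the network is rewired (degree
    preserved) and the node scores independently permuted; p is the
    fraction of replicates whose shortest source-target length is strictly
    smaller than the observed one. Disconnected replicates count as
    not-shorter. Requires the observed path to be finite.
    """
    obs = shortest_path(network, source, target, scores)
    observed = obs.weighted_len if weighted else obs.unweighted_len
    if not np.isfinite(observed):
        raise ValueError(
            f"observed {source}->{target} path is disconnected; "
            "permutation p undefined"
        )
    # insertion order, not label order: keeps the test equivariant under
    # order-preserving relabeling of the graph
    nodes = list(network.nodes)
    count = 0
    for b in range(1, n_perm + 1):
        s_rewire, s_scores = _perm_seeds(seed, b)
        net_b = rewire_network(network, s_rewire)
        if weighted and scores is not None:
            scores_b = _permute_scores(scores, nodes, s_scores)
            adj = {u: sorted(net_b[u]) for u in net_b}
            length, _ = _weighted_shortest(adj, source, target, scores_b.score)
        else:
            try:
                length = float(nx.shortest_path_length(net_b, source, target))
            except nx.NetworkXNoPath:
                length = inf
        if length < observed:
            count += 1
    if estimator == "add_one":
        return (count + 1) / (n_perm + 1)
    return count / n_perm


def path_permutation_null(network: nx.Graph, scores: Optional[NodeScoreMap],
                          pairs: Sequence[tuple[str, str]], n_perm: int,
                          seed: int, weighted: bool = False,
                          estimator: str = "plain") -> list[Optional[float]]:
    """Permutation p for many source-target pairs, sharing the rewired
    networks across pairs (one null draw per replicate serves every pair).

    Returns one p per pair, None where the observed path is disconnected.
    Used for large calibration runs; `path_permutation_p` is the per-pair
    equivalent.
    """
    observed: list[float] = []
    for s, t in pairs:
        res = shortest_path(network, s, t, scores)
        observed.append(res.weighted_len if weighted else res.unweighted_len)
    counts = np.zeros(len(pairs))
    nodes = list(network.nodes)
    for b in range(1, n_perm + 1):
        s_rewire, s_scores = _perm_seeds(seed, b)
        net_b = rewire_network(network, s_rewire)
        if weighted and scores is not None:
            scores_b = _permute_scores(scores, nodes, s_scores)
            adj = {u: sorted(net_b[u]) for u in net_b}
            by_source: dict[str, dict[str, float]] = {}
            for k, (s, t) in enumerate(pairs):
                if not np.isfinite(observed[k]):
                    continue
                if s not in by_source:
                    by_source[s] = _weighted_lengths_from(adj, s, scores_b.score)
                if by_source[s].get(t, inf) < observed[k]:
                    counts[k] += 1
        else:
            lengths_cache: dict[str, dict] = {}
            for k, (s, t) in enumerate(pairs):
                if not np.isfinite(observed[k]):
                    continue
                if s not in lengths_cache:
                    lengths_cache[s] = nx.single_source_shortest_path_length(
                        net_b, s)
                if lengths_cache[s].get(t, inf) < observed[k]:
                    counts[k] += 1
    out: list[Optional[float]] = []
    for k in range(len(pairs)):
        if not np.isfinite(observed[k]):
            out.append(None)
        elif estimator == "add_one":
            out.append((counts[k] + 1) / (n_perm + 1))
        else:
            out.append(counts[k] / n_perm)
    return out


def _weighted_lengths_from(adj: dict, source: str, score) -> dict[str, float]:
    """Single-source node-weighted Dijkstra lengths."""
    dist = {source: 0.0}
    heap = [(0.0, source)]
    done: set[str] = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v in adj[u]:
            nd = d + score(v)
            if v not in dist or nd < dist[v] - 1e-15:
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return {u: dist[u] for u in done}


# ---------------------------------------------------------------------------
# evidence integration (Table-2 shape)
# ---------------------------------------------------------------------------


def integrate_evidence(trans_loci: Sequence[tuple[str, PqtlLocus]],
                       annotation: Sequence[GeneModel],
                       variants: Sequence[Variant],
                       ld_ref: GenotypeMatrix,
                       datasets: Sequence[EqtlDataset],
                       network: nx.Graph,
                       trait_gene_of: dict[str, str],
                       literature_counts: Optional[dict[tuple[str, str], int]] = None,
                       config: Optional[RunConfig] = None
                       ) -> tuple[list[EvidenceRow], list[EvidenceRow]]:
    """Score all five evidence tracks for every (index SNP, cis-gene) pair.

    ``trans_loci`` is a list of (trait protein, classified trans locus);
    ``trait_gene_of`` maps a trait protein to its encoding gene symbol.
    Returns (headline rows: >= 1 criterion fired, full unfiltered rows).
    """
    cfg = config or RunConfig()
    headline: list[EvidenceRow] = []
    full: list[EvidenceRow] = []
    for trait, locus in trans_loci:
        snp = locus.index.variant
        trait_gene = trait_gene_of.get(trait)
        scores = trans_eqtl_scores(snp, datasets, network.nodes,
                                   cfg.eqtl_w1_p, cfg.eqtl_w2_p)
        trait_gene_ok = trait_gene is not None and trait_gene in network
        if not trait_gene_ok:
            logger.info("trait gene for %s absent from network; "
                        "pathway tracks skipped", trait)
        proxy = coding_proxy_evidence(snp, variants, ld_ref, cfg.coding_r2,
                                      cfg.cis_window_kb)
        for gene, dist_kb, rank in enumerate_cis_genes(snp, annotation,
                                                       cfg.cis_window_kb):
            row = EvidenceRow(trait=trait, index_snp=snp.id,
                              cis_gene=gene.symbol, distance_kb=dist_kb,
                              dist_rank=rank)
            # a coding proxy is evidence for the gene harboring the missense
            # variant, not for every candidate at the locus
            if proxy is not None and gene.start <= proxy[0].pos <= gene.end:
                row.coding_proxy = _proxy_as_ids(proxy)
            row.cis_eqtl_hits = cis_eqtl_scan(snp, gene.symbol, datasets,
                                              cfg.eqtl_cis_p)
            if (trait_gene_ok and gene.symbol in network
                    and gene.symbol != trait_gene):
                res = shortest_path(network, gene.symbol, trait_gene, scores)
                if np.isfinite(res.unweighted_len):
                    p_unw = path_permutation_p(
                        network, None, gene.symbol, trait_gene,
                        n_perm=cfg.n_perm, seed=cfg.seed, weighted=False,
                        estimator=cfg.perm_estimator)
                    row.unweighted_perm_p = p_unw
                    row.unweighted_path_sig = p_unw < cfg.perm_alpha
                if np.isfinite(res.weighted_len):
                    p_w = path_permutation_p(
                        network, scores, gene.symbol, trait_gene,
                        n_perm=cfg.n_perm, seed=cfg.seed, weighted=True,
                        estimator=cfg.perm_estimator)
                    if p_w < cfg.perm_alpha:
                        via = "|".join(res.weighted_nodes[1:-1]) or "direct"
                        row.weighted_path = (via, p_w)
            if literature_counts is not None:
                row.literature_score = literature_counts.get(
                    (snp.id, gene.symbol))
            full.append(row)
            if row.criteria_fired(cfg.lit_min):
                headline.append(row)
    return headline, full


def _proxy_as_ids(hit: Optional[tuple[Variant, float]]
                  ) -> Optional[tuple[str, float]]:
    return None if hit is None else (hit[0].id, hit[1])


def evidence_frame(rows: Sequence[EvidenceRow]):
    """Tabular (Table-2 shaped) view of evidence rows."""
    import pandas as pd

    return pd.DataFrame([
        {
            "trait": r.trait,
            "index_snp": r.index_snp,
            "cis_gene": r.cis_gene,
            "distance_kb": r.distance_kb,
            "dist_rank": r.dist_rank,
            "coding_proxy": (f"{r.coding_proxy[0]} (r2={r.coding_proxy[1]:.2f})"
                             if r.coding_proxy else ""),
            "cis_eqtl": "; ".join(f"{d} (P={p:.2g})" for d, p in r.cis_eqtl_hits),
            "unweighted_path": "yes" if r.unweighted_path_sig else "",
            "weighted_path": (f"via {r.weighted_path[0]} (P={r.weighted_path[1]:.3g})"
                              if r.weighted_path else ""),
            "literature_score": r.literature_score,
        }
        for r in rows
    ])
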