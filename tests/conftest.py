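"""Shared fixtures and independent oracle implementations.

Oracles here deliberately use different algorithms from the package
(exact rational enumeration, brute-force path enumeration, direct
step-up scans) so agreement is meaningful.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, inf

import networkx as nx
import numpy as np
import pytest

from pqtlkit import GenotypeMatrix, Variant


def make_variant(vid="rs1", chrom="1", pos=1000, coded="A", other="G",
                 missense=False, freq=None):
    return Variant(id=vid, chrom=chrom, pos=pos, coded_allele=coded,
                   other_allele=other, missense=missense, coded_freq=freq)


def make_gm(dosage, variants=None, samples=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if variants is None:
        variants = [make_variant(f"rs{j + 1}", "1", 1000 + 1000 * j)
                    for j in range(m)]
    if samples is None:
        samples = [f"S{i + 1}" for i in range(n)]
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Exact HWE p by full rational enumeration over heterozygote counts."""
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return 1.0
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    rare, common = min(n_A, n_a), max(n_A, n_a)
    if rare == 0:
        return 1.0

    def weight(h):
        # multinomial genotype count x 2^h, exact
        hom_rare = (rare - h) // 2
        hom_common = (common - h) // 2
        num = Fraction(2) ** h
        # N! / (hom_rare! h! hom_common!)
        ways = Fraction(1)
        remaining = n
        for block in (hom_rare, h, hom_common):
            ways *= comb(remaining, block)
            remaining -= block
        return ways * num

    hs = list(range(rare % 2, rare + 1, 2))
    ws = {h: weight(h) for h in hs}
    total = sum(ws.values())
    w_obs = ws[n_Aa]
    p = sum(w for w in ws.values() if w <= w_obs) / total
    return float(p)


def ols_oracle(x, y):
    """Matrix-algebra simple regression via the normal equations."""
    X = np.column_stack([np.ones_like(x), x])
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    n = len(y)
    sigma2 = resid @ resid / (n - 2)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    return float(beta[1]), float(se)


def path_enumeration_oracle(graph, source, target, scores=None):
    """Min hop count and min node-score cost over all simple paths."""
    best_u, best_w = inf, inf
    for path in nx.all_simple_paths(graph, source, target):
        hops = len(path) - 1
        cost = sum((scores or {}).get(node, 1.0) for node in path[1:])
        best_u = min(best_u, hops)
        best_w = min(best_w, cost)
    return best_u, best_w


def bh_oracle(pvals, q):
    """Direct step-up: largest k with p_(k) <= k q / m; flag all p <= p_(k)."""
    m = len(pvals)
    order = np.argsort(pvals)
    thresh = 0.0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank * q / m:
            thresh = pvals[idx]
    return np.asarray([p <= thresh and thresh > 0 for p in pvals])


def gls_oracle(betas, ses):
    """Intercept-only weighted least squares as the IVW cross-check."""
    w = 1.0 / np.asarray(ses) ** 2
    var = 1.0 / w.sum()
    est = var * (w * np.asarray(betas)).sum()
    return est, np.sqrt(var)


@pytest.fixture
def line_network():
    """A - B - C - D path with a pendant E on B."""
    g = nx.Graph()
    for a, b in [("A", "B"), ("B", "C"), ("C", "D"), ("B", "E")]:
        g.add_edge(a, b, confidence=900)
    return g
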