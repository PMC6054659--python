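"""Independent straight-line oracles used by the test suite.

Each function here is a deliberately plain, loop-based transcription of the
published formula or a brute-force enumeration, written separately from the
vectorized library code it checks.
"""

from __future__ import annotations

import numpy as np


def wc_abc_oracle(genotype_counts: list[tuple[int, int, int]]):
    """Weir-Cockerham a, b, c from per-population genotype counts.

    ``genotype_counts[i] = (n0, n1, n2)``: individuals with dosage 0, 1, 2 in
    population i. Straight-line transcription of the published
    variance-component formulas for one biallelic locus.
    """
    r = len(genotype_counts)
    n = [n0 + n1 + n2 for (n0, n1, n2) in genotype_counts]
    p = [
        (2 * n2 + n1) / (2 * ni)
        for (n0, n1, n2), ni in zip(genotype_counts, n)
    ]
    h = [n1 / ni for (n0, n1, n2), ni in zip(genotype_counts, n)]

    nbar = sum(n) / r
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def r2_enumeration_oracle(hap_a: list[int], hap_b: list[int]) -> float:
    """r2 by enumerating the four two-locus haplotype classes."""
    n = len(hap_a)
    n00 = n01 = n10 = n11 = 0
    for x, y in zip(hap_a, hap_b):
        if x == 0 and y == 0:
            n00 += 1
        elif x == 0 and y == 1:
            n01 += 1
        elif x == 1 and y == 0:
            n10 += 1
        else:
            n11 += 1
    p11 = n11 / n
    p_a = (n10 + n11) / n
    p_b = (n01 + n11) / n
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom == 0:
        return float("nan")
    d = p11 - p_a * p_b
    return d * d / denom


def ehhs_string_oracle(haplotypes: list[str], focal: int, x: int) -> float:
    """EHHS(s, x) by grouping haplotype strings over the inclusive span.

    ``haplotypes`` are strings of '0'/'1'; the span runs from min(focal, x)
    to max(focal, x) inclusive.
    """
    n = len(haplotypes)
    lo, hi = min(focal, x), max(focal, x)

    def homozygosity(keys: list[str]) -> float:
        tally: dict[str, int] = {}
        for k in keys:
            tally[k] = tally.get(k, 0) + 1
        return sum(c * (c - 1) for c in tally.values()) / (n * (n - 1))

    h_sx = homozygosity([h[lo : hi + 1] for h in haplotypes])
    h_ss = homozygosity([h[focal] for h in haplotypes])
    return h_sx / h_ss


def overlap_oracle(
    intervals: list[tuple[str, int, int]],
    genes: list[tuple[str, str, int, int]],
    flank: int = 0,
) -> set[str]:
    """All-pairs >= 1 bp overlap check (1-based inclusive coordinates)."""
    hits = set()
    for g_id, g_chrom, g_start, g_end in genes:
        for chrom, start, end in intervals:
            if g_chrom != chrom:
                continue
            if g_start - flank <= end and g_end + flank >= start:
                hits.add(g_id)
    return hits


def hypergeom_tail_oracle(k: int, big_n: int, big_k: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by direct summation."""
    from math import comb

    total = 0
    for j in range(k, min(big_k, n) + 1):
        total += comb(big_k, j) * comb(big_n - big_k, n - j)
    return total / comb(big_n, n)


def bh_oracle(p: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up by its definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, m * p[i] / rank_from_top)
        adj[i] = running_min
    return [min(x, 1.0) for x in adj]


def additive_distance_from_tree(
    edges: dict[tuple[str, str], float], leaves: list[str]
) -> np.ndarray:
    """Leaf-to-leaf path-length matrix of an undirected weighted tree."""
    import networkx as nx

    g = nx.Graph()
    for (u, v), w in edges.items():
        g.add_edge(u, v, weight=w)
    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        lengths = nx.single_source_dijkstra_path_length(g, leaves[i], weight="weight")
        for j in range(n):
            d[i, j] = lengths[leaves[j]]
    return d
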