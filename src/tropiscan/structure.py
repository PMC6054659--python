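"""Population structure: smartpca-style PCA and a neighbor-joining tree on
allele-sharing (p-)distances with bootstrap support.

PCA follows the EIGENSOFT normalization: missing dosages are mean-imputed per
locus, the allele frequency is estimated with a pseudocount,
p_hat = (1 + sum g) / (2 + 2 n), and entries are scaled as
(g - 2 p_hat) / sqrt(2 p_hat (1 - p_hat)) before the eigendecomposition of
the sample covariance.

The p-distance analogue on genotypes is the allele-sharing distance
d_ij = mean over complete loci of (2 - IBS_ij) / 2, i.e. |g_i - g_j| / 2 for
dosages — the proportion of allele differences per site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix

__all__ = [
    "PcaResult",
    "PhyloTree",
    "pca",
    "allele_sharing_distance",
    "neighbor_joining",
    "bootstrap_support",
]


@dataclass(frozen=True)
class PcaResult:
    sample_ids: np.ndarray
    coordinates: np.ndarray  # samples x components
    eigenvalues: np.ndarray  # non-increasing

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates,
            columns=[f"PC{k + 1}" for k in range(self.coordinates.shape[1])],
        )
        df.insert(0, "id", self.sample_ids)
        return df


class _Node:
    __slots__ = ("name", "children", "length")

    def __init__(self, name=None, children=None, length=0.0):
        self.name = name
        self.children = children or []
        self.length = length

    def leaves(self) -> frozenset:
        if not self.children:
            return frozenset([self.name])
        out = frozenset()
        for c in self.children:
            out |= c.leaves()
        return out


@dataclass
class PhyloTree:
    """Unrooted tree: taxa, newick, and the leaf bipartition per internal edge.

    ``support`` maps each internal-edge bipartition (a frozenset holding the
    smaller side's leaves) to a bootstrap fraction; empty when no bootstrap
    was run.
    """

    taxa: list[str]
    root: _Node
    support: dict[frozenset, float] = field(default_factory=dict)

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions, each as its smaller (or
        lexicographically first, on a tie) side."""
        all_leaves = frozenset(self.taxa)
        out: set[frozenset] = set()

        def walk(node: _Node) -> None:
            for child in node.children:
                side = child.leaves()
                other = all_leaves - side
                if len(side) >= 2 and len(other) >= 2:
                    if len(side) < len(other) or (
                        len(side) == len(other) and sorted(side) < sorted(other)
                    ):
                        out.add(side)
                    else:
                        out.add(other)
                walk(child)

        walk(self.root)
        return out

    def _newick(self, node: _Node, with_support: bool) -> str:
        if not node.children:
            return f"{node.name}:{node.length:.6g}"
        inner = ",".join(self._newick(c, with_support) for c in node.children)
        label = ""
        if with_support and self.support:
            side = node.leaves()
            other = frozenset(self.taxa) - side
            key = min(
                (s for s in (side, other) if s in self.support),
                default=None,
                key=len,
            )
            if key is not None:
                label = f"{self.support[key]:.2f}"
        return f"({inner}){label}:{node.length:.6g}"

    def to_newick(self, with_support: bool = True) -> str:
        inner = ",".join(self._newick(c, with_support) for c in self.root.children)
        return f"({inner});"


def pca(g: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """EIGENSOFT-normalized PCA of the genotype matrix.

    Monomorphic loci (among observed calls) are dropped; missing dosages are
    mean-imputed per locus after normalization (i.e. contribute 0).
    Deterministic up to component sign.
    """
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = g.dosage.astype(float)
    missing = g.dosage == MISSING
    d[missing] = np.nan
    n_called = (~missing).sum(axis=0)
    totals = np.nansum(d, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_obs = totals / (2.0 * n_called)
    poly = (n_called > 0) & (p_obs > 0) & (p_obs < 1)
    d = d[:, poly]
    p_hat = (1.0 + totals[poly]) / (2.0 + 2.0 * n_called[poly])

    x = (d - 2.0 * p_hat) / np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    x[np.isnan(x)] = 0.0
    x -= x.mean(axis=0)

    rank = min(x.shape)
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; truncating",
            UserWarning,
            stacklevel=2,
        )
        n_components = rank
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eigenvalues = (s**2) / (g.n_samples - 1)
    coords = u[:, :n_components] * s[:n_components]
    return PcaResult(
        sample_ids=g.samples.ids.copy(),
        coordinates=coords,
        eigenvalues=eigenvalues[:n_components],
    )


def _allele_sharing_from_dosage(
    dosage: np.ndarray, sample_ids: np.ndarray
) -> np.ndarray:
    n = dosage.shape[0]
    d = dosage.astype(float)
    ok = dosage != MISSING
    dist = np.zeros((n, n))
    for i in range(n):
        both = ok[i] & ok[i + 1 :]
        n_loci = both.sum(axis=1)
        diffs = np.where(both, np.abs(d[i] - d[i + 1 :]), 0.0).sum(axis=1)
        if np.any(n_loci == 0):
            j = int(i + 1 + np.flatnonzero(n_loci == 0)[0])
            raise ValueError(
                f"samples {sample_ids[i]!r} and {sample_ids[j]!r} share "
                "no complete loci"
            )
        dist[i, i + 1 :] = dist[i + 1 :, i] = diffs / (2.0 * n_loci)
    return dist


def _distance_frame(
    dosage: np.ndarray,
    sample_ids: np.ndarray,
    populations: np.ndarray,
    level: str,
) -> pd.DataFrame:
    dist = _allele_sharing_from_dosage(dosage, sample_ids)
    if level == "individuals":
        ids = [str(s) for s in sample_ids]
        return pd.DataFrame(dist, index=ids, columns=ids)
    if level != "populations":
        raise ValueError("level must be 'individuals' or 'populations'")
    pops = list(pd.unique(populations))
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    idx = {p: np.flatnonzero(populations == p) for p in pops}
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            block = dist[np.ix_(idx[pops[i]], idx[pops[j]])]
            out.iloc[i, j] = out.iloc[j, i] = block.mean()
    return out


def allele_sharing_distance(
    g: GenotypeMatrix, level: str = "individuals"
) -> pd.DataFrame:
    """Allele-sharing (p-)distance matrix over individuals or populations.

    Individual level: d_ij = mean over loci complete in both individuals of
    |g_i - g_j| / 2. Population level: mean of d_ij over all cross-population
    individual pairs.
    """
    if g.n_samples < 2:
        raise ValueError("need at least 2 taxa")
    return _distance_frame(
        g.dosage, g.samples.ids, g.samples.populations, level
    )


def neighbor_joining(d: pd.DataFrame | np.ndarray, taxa=None) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The Q-criterion minimum is taken at the smallest (i, j) taxon-index pair
    on ties; negative branch lengths are clamped to 0 (the deficit is moved
    nowhere — simple clamping, as in common NJ implementations).
    """
    if isinstance(d, pd.DataFrame):
        taxa = [str(t) for t in d.index]
        dm = d.to_numpy(dtype=float).copy()
    else:
        dm = np.asarray(d, dtype=float).copy()
        if taxa is None:
            taxa = [f"t{k}" for k in range(dm.shape[0])]
        taxa = list(taxa)
    n = dm.shape[0]
    if dm.shape != (n, n) or not np.allclose(dm, dm.T, atol=1e-9):
        raise ValueError("distance matrix must be square and symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    np.fill_diagonal(dm, 0.0)

    nodes: list[_Node] = [_Node(name=t) for t in taxa]
    active = list(range(n))
    dist = dm

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major argmin over the upper triangle = smallest (i, j) on ties
        iu, ju = np.triu_indices(m, k=1)
        best = int(np.argmin(q[iu, ju]))
        a, b = int(iu[best]), int(ju[best])
        i, j = active[a], active[b]

        d_ij = sub[a, b]
        la = 0.5 * d_ij + (totals[a] - totals[b]) / (2.0 * (m - 2))
        lb = d_ij - la
        la, lb = max(la, 0.0), max(lb, 0.0)

        child_a, child_b = nodes[i], nodes[j]
        child_a.length, child_b.length = la, lb
        new = _Node(children=[child_a, child_b])
        nodes.append(new)
        k_new = len(nodes) - 1

        new_d = 0.5 * (dist[i, active] + dist[j, active] - d_ij)
        grown = np.zeros((k_new + 1, k_new + 1))
        grown[: dist.shape[0], : dist.shape[1]] = dist
        grown[k_new, active] = new_d
        grown[active, k_new] = new_d
        dist = grown

        active = [x for x in active if x not in (i, j)] + [k_new]

    # resolve the final three nodes around one central vertex
    i, j, k = active
    d_ij, d_ik, d_jk = dist[i, j], dist[i, k], dist[j, k]
    li = max(0.5 * (d_ij + d_ik - d_jk), 0.0)
    lj = max(0.5 * (d_ij + d_jk - d_ik), 0.0)
    lk = max(0.5 * (d_ik + d_jk - d_ij), 0.0)
    for node, ln in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.length = ln
    root = _Node(children=[nodes[i], nodes[j], nodes[k]])
    return PhyloTree(taxa=list(taxa), root=root)


def bootstrap_support(
    g: GenotypeMatrix,
    level: str = "individuals",
    n_boot: int = 100,
    seed: int | None = None,
) -> PhyloTree:
    """NJ tree on the full data with per-edge bootstrap support.

    Loci are resampled with replacement ``n_boot`` times; the support of each
    internal edge of the full-data tree is the fraction of replicate trees
    containing the same leaf bipartition. ``n_boot=0`` returns the tree with
    no support fields.
    """
    full = neighbor_joining(allele_sharing_distance(g, level=level))
    if n_boot == 0:
        return full
    rng = np.random.default_rng(seed)
    targets = full.bipartitions()
    hits = {bp: 0 for bp in targets}
    for _ in range(n_boot):
        idx = rng.integers(g.n_markers, size=g.n_markers)
        rep = neighbor_joining(
            _distance_frame(
                g.dosage[:, idx], g.samples.ids, g.samples.populations, level
            )
        )
        rep_bps = rep.bipartitions()
        for bp in targets:
            if bp in rep_bps:
                hits[bp] += 1
    full.support = {bp: hits[bp] / n_boot for bp in targets}
    return full
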