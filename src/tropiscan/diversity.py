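"""Weir & Cockerham (1984) Fst: variance components, multilocus estimator,
pairwise population matrix, and a label-permutation significance test.

Per locus and per population the method needs the diploid sample size n_i
(non-missing calls only; complete-case within each population), the alt-allele
frequency p_i and the observed heterozygote frequency h_i. From these the
among-population (a), among-individual-within-population (b) and
within-individual (c) variance components are formed; the multilocus estimator
is the ratio of sums

    theta_hat = sum_l a_l / sum_l (a_l + b_l + c_l)

over informative loci. Loci where a + b + c = 0 (e.g. monomorphic across the
populations considered) carry no information about differentiation and are
excluded from the ratio. Negative estimates are reported as-is, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix

__all__ = [
    "FstComponents",
    "PermutationResult",
    "wc_components",
    "multilocus_fst",
    "pairwise_fst_matrix",
    "fst_permutation_test",
]


@dataclass(frozen=True)
class FstComponents:
    """Per-locus Weir-Cockerham variance components.

    ``informative`` is False where fewer than two populations have calls,
    where the mean sample size is <= 1, or where a + b + c = 0.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    informative: np.ndarray

    def per_locus_theta(self) -> np.ndarray:
        tot = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.where(self.informative, self.a / tot, np.nan)
        return theta


@dataclass(frozen=True)
class PermutationResult:
    observed_theta: float
    null_thetas: np.ndarray
    p_value: float


def _pop_locus_stats(dosage: np.ndarray, groups: list[np.ndarray]):
    """Per population x locus: sample size n, alt freq p, observed het h."""
    r = len(groups)
    n_loci = dosage.shape[1]
    n = np.zeros((r, n_loci))
    p = np.zeros((r, n_loci))
    h = np.zeros((r, n_loci))
    for k, idx in enumerate(groups):
        d = dosage[idx, :]
        called = d != MISSING
        n[k] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(called, d, 0).sum(axis=0) / (2.0 * n[k])
            h[k] = (d == 1).sum(axis=0) / n[k]
    return n, p, h


def _components_from_stats(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> FstComponents:
    present = n > 0
    r_l = present.sum(axis=0).astype(float)

    n = np.where(present, n, 0.0)
    p = np.where(present, p, 0.0)
    h = np.where(present, h, 0.0)

    n_tot = n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_tot / r_l
        nc = (n_tot - (n**2).sum(axis=0) / n_tot) / (r_l - 1.0)
        pbar = (n * p).sum(axis=0) / n_tot
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r_l - 1.0) * nbar)
        hbar = (n * h).sum(axis=0) / n_tot

        inner = pbar * (1 - pbar) - (r_l - 1.0) / r_l * s2
        a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0

    informative = (r_l >= 2) & (nbar > 1) & (nc > 0)
    a = np.where(informative, a, 0.0)
    b = np.where(informative, b, 0.0)
    c = np.where(informative, c, 0.0)
    informative = informative & ((a + b + c) != 0)
    return FstComponents(a=a, b=b, c=c, informative=informative)


def wc_components(
    g: GenotypeMatrix, populations: list[str] | None = None
) -> FstComponents:
    """Weir-Cockerham a, b, c for every locus over the given populations.

    Missing data are handled complete-case within each population, so the
    per-population sample sizes n_i vary by locus.
    """
    if populations is None:
        populations = list(pd.unique(g.samples.populations))
    if len(populations) < 2:
        raise ValueError("need at least 2 populations")
    groups = [
        np.flatnonzero(g.samples.populations == pop) for pop in populations
    ]
    n, p, h = _pop_locus_stats(g.dosage, groups)
    return _components_from_stats(n, p, h)


def multilocus_fst(components: FstComponents) -> float:
    """Ratio-of-sums theta over informative loci (may be slightly negative)."""
    ok = components.informative
    if not ok.any():
        raise ValueError("no informative loci")
    denom = (components.a + components.b + components.c)[ok].sum()
    return float(components.a[ok].sum() / denom)


def _theta_from_groups(dosage: np.ndarray, groups: list[np.ndarray]) -> float:
    n, p, h = _pop_locus_stats(dosage, groups)
    return multilocus_fst(_components_from_stats(n, p, h))


def pairwise_fst_matrix(g: GenotypeMatrix) -> pd.DataFrame:
    """Symmetric population x population multilocus Fst matrix (diagonal 0)."""
    import warnings

    pops = list(pd.unique(g.samples.populations))
    if len(pops) < 2:
        raise ValueError("need at least 2 population labels")
    for pop in pops:
        if (g.samples.populations == pop).sum() < 2:
            warnings.warn(
                f"population {pop!r} has <2 individuals; Fst computed anyway",
                UserWarning,
                stacklevel=2,
            )
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            comp = wc_components(g, [pops[i], pops[j]])
            theta = multilocus_fst(comp)
            mat.iloc[i, j] = theta
            mat.iloc[j, i] = theta
    return mat


def fst_permutation_test(
    g: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    n_perm: int = 1000,
    seed: int | None = None,
) -> PermutationResult:
    """Label-randomization test of the observed Fst between two populations.

    Each replicate shuffles the individuals of the two populations between the
    two labels (group sizes preserved) and recomputes the multilocus theta.
    The p-value uses the add-one rule p = (1 + #{null >= observed}) / (n_perm + 1),
    so it is never zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if pop_a == pop_b:
        raise ValueError("pop_a and pop_b must differ")
    idx_a = np.flatnonzero(g.samples.populations == pop_a)
    idx_b = np.flatnonzero(g.samples.populations == pop_b)
    pool = np.concatenate([idx_a, idx_b])
    dosage = g.dosage
    observed = _theta_from_groups(dosage, [idx_a, idx_b])

    rng = np.random.default_rng(seed)
    n_a = len(idx_a)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(pool)
        null[k] = _theta_from_groups(dosage, [perm[:n_a], perm[n_a:]])
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return PermutationResult(
        observed_theta=observed, null_thetas=null, p_value=float(p)
    )
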