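"""Pairwise linkage disequilibrium (r2) and distance-binned decay profiles.

r2 is the squared allele-frequency correlation between two loci,

    r2 = D^2 / (p_A (1 - p_A) p_B (1 - p_B)),   D = p_AB - p_A p_B.

From phased haplotypes the four haplotype classes are counted directly. From
unphased genotypes the haplotype frequencies are estimated by EM: only the
double-heterozygote genotype class is phase-ambiguous, and it is split
between the coupling (00/11) and repulsion (01/10) resolutions according to
the current frequency iterate. EM is initialised at linkage equilibrium
(products of the single-locus frequencies) so results are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix, HaplotypeSet

__all__ = ["r2_phased", "r2_unphased_em", "ld_decay_profile", "LdDecayProfile"]


def _r2_from_hap_freqs(x: np.ndarray) -> float:
    """r2 from haplotype frequencies ordered (x00, x01, x10, x11)."""
    p_a = x[2] + x[3]  # alt at first locus
    p_b = x[1] + x[3]  # alt at second locus
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0:
        return np.nan
    d = x[3] - p_a * p_b
    return float(d * d / denom)


def r2_phased(h: HaplotypeSet, locus_i: int, locus_j: int) -> float:
    """r2 from phased haplotype counts; NaN if either locus is monomorphic."""
    a = h.alleles[:, locus_i].astype(np.int64)
    b = h.alleles[:, locus_j].astype(np.int64)
    n = len(a)
    counts = np.bincount(2 * a + b, minlength=4)
    return _r2_from_hap_freqs(counts / n)


def em_haplotype_freqs(
    g: GenotypeMatrix,
    locus_i: int,
    locus_j: int,
    tol: float = 1e-8,
    max_iter: int = 1000,
    return_loglik: bool = False,
) -> np.ndarray | tuple[np.ndarray, list[float]]:
    """EM estimate of the four two-locus haplotype frequencies (x00,x01,x10,x11).

    Complete-case individuals only. With ``return_loglik`` the per-iteration
    observed-data log-likelihood trace is returned as well (non-decreasing).
    """
    gi = g.dosage[:, locus_i]
    gj = g.dosage[:, locus_j]
    ok = (gi != MISSING) & (gj != MISSING)
    gi, gj = gi[ok].astype(np.int64), gj[ok].astype(np.int64)
    n = len(gi)
    if n < 2:
        raise ValueError("need >=2 individuals complete at both loci")

    # 3x3 genotype-pair counts
    counts = np.bincount(3 * gi + gj, minlength=9).reshape(3, 3)
    n_hap = 2.0 * n

    p_a = gi.sum() / n_hap
    p_b = gj.sum() / n_hap
    x = np.array(
        [
            (1 - p_a) * (1 - p_b),
            (1 - p_a) * p_b,
            p_a * (1 - p_b),
            p_a * p_b,
        ]
    )

    # unambiguous haplotype tallies from the 8 phase-certain genotype classes
    base = np.zeros(4)
    base[0] = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    base[1] = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    base[2] = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    base[3] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    n_dh = counts[1, 1]  # double heterozygotes: coupling (00,11) vs repulsion (01,10)

    def loglik(x: np.ndarray) -> float:
        with np.errstate(divide="ignore"):
            lx = np.log(np.where(x > 0, x, 1.0))
        ll = float(base @ lx)
        dh = 2 * (x[0] * x[3] + x[1] * x[2])
        if n_dh:
            ll += n_dh * (np.log(dh) if dh > 0 else -np.inf)
        return ll

    trace = [loglik(x)] if return_loglik else None
    converged = n_dh == 0
    for _ in range(max_iter):
        coup = x[0] * x[3]
        rep = x[1] * x[2]
        tot = coup + rep
        w = 0.5 if tot <= 0 else coup / tot
        new = base.copy()
        new[0] += n_dh * w
        new[3] += n_dh * w
        new[1] += n_dh * (1 - w)
        new[2] += n_dh * (1 - w)
        new /= n_hap
        delta = np.abs(new - x).max()
        x = new
        if trace is not None:
            trace.append(loglik(x))
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"haplotype-frequency EM did not converge in {max_iter} iterations; "
            "returning last iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    if n_dh == 0:
        x = base / n_hap
    return (x, trace) if trace is not None else x


def r2_unphased_em(
    g: GenotypeMatrix,
    locus_i: int,
    locus_j: int,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> float:
    """Genotype r2 via EM haplotype frequencies; NaN if a locus is monomorphic."""
    x = em_haplotype_freqs(g, locus_i, locus_j, tol=tol, max_iter=max_iter)
    return _r2_from_hap_freqs(np.asarray(x))


@dataclass(frozen=True)
class LdDecayProfile:
    """Mean r2 per physical-distance bin, per population."""

    table: pd.DataFrame  # columns: population, bin_lo_bp, bin_hi_bp, mean_r2, n_pairs, empty

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _pairs_within(pos: np.ndarray, max_dist: int) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i, j>i) on one chromosome with gap <= max_dist."""
    ii, jj = [], []
    n = len(pos)
    hi = 0
    for i in range(n):
        if hi < i + 1:
            hi = i + 1
        while hi < n and pos[hi] - pos[i] <= max_dist:
            hi += 1
        ii.extend([i] * (hi - i - 1))
        jj.extend(range(i + 1, hi))
    return np.asarray(ii, dtype=np.int64), np.asarray(jj, dtype=np.int64)


def _phased_r2_pairs(alleles: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    """Vectorized phased r2 for many locus pairs (NaN where monomorphic)."""
    a = alleles.astype(np.float64)
    p = a.mean(axis=0)
    n = a.shape[0]
    pab = (a[:, ii] * a[:, jj]).sum(axis=0) / n
    d = pab - p[ii] * p[jj]
    denom = p[ii] * (1 - p[ii]) * p[jj] * (1 - p[jj])
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, d * d / denom, np.nan)
    return r2


def ld_decay_profile(
    data: HaplotypeSet | GenotypeMatrix,
    max_dist_bp: int = 1_000_000,
    bin_width_bp: int = 10_000,
    populations: list[str] | None = None,
) -> LdDecayProfile:
    """Distance-binned mean r2, computed separately per population label.

    All intra-chromosomal marker pairs with gap <= ``max_dist_bp`` enter their
    half-open bin [lo, hi); no marker is excluded or pruned. From a
    :class:`HaplotypeSet` the phased estimator is used; from a
    :class:`GenotypeMatrix` the EM genotype estimator.
    """
    phased = isinstance(data, HaplotypeSet)
    if populations is None:
        pops = list(pd.unique(data.populations if phased else data.samples.populations))
    else:
        pops = list(populations)

    edges = np.arange(0, max_dist_bp + bin_width_bp, bin_width_bp)
    rows = []
    markers = data.markers
    for pop in pops:
        sub = (
            data.restrict_population(pop)
            if phased
            else data.restrict_populations([pop])
        )
        for chrom in pd.unique(markers.chrom):
            on_c = np.flatnonzero(markers.chrom == chrom)
            pos = markers.pos_bp[on_c]
            ii, jj = _pairs_within(pos, max_dist_bp)
            if len(ii) == 0:
                continue
            gaps = pos[jj] - pos[ii]
            if phased:
                r2 = _phased_r2_pairs(sub.alleles[:, on_c], ii, jj)
            else:
                r2 = np.array(
                    [
                        r2_unphased_em(sub, int(on_c[i]), int(on_c[j]))
                        for i, j in zip(ii, jj)
                    ]
                )
            ok = ~np.isnan(r2)
            which = np.digitize(gaps[ok], edges) - 1
            # bins are half-open [lo, hi) except the last, which closes at max_dist
            which = np.where(gaps[ok] == edges[-1], len(edges) - 2, which)
            rows.append(
                pd.DataFrame(
                    {"population": pop, "bin": which, "r2": r2[ok]}
                )
            )
    if rows:
        long = pd.concat(rows, ignore_index=True)
    else:
        long = pd.DataFrame({"population": [], "bin": [], "r2": []})

    out = []
    for pop in pops:
        sub = long[long["population"] == pop]
        grouped = sub.groupby("bin")["r2"]
        means = grouped.mean()
        counts = grouped.size()
        for b in range(len(edges) - 1):
            n_pairs = int(counts.get(b, 0))
            out.append(
                {
                    "population": pop,
                    "bin_lo_bp": int(edges[b]),
                    "bin_hi_bp": int(edges[b + 1]),
                    "mean_r2": float(means.get(b, np.nan)),
                    "n_pairs": n_pairs,
                    "empty": n_pairs == 0,
                }
            )
    return LdDecayProfile(table=pd.DataFrame(out))
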