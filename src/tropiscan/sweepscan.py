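"""Site-EHH selection scan: EHHS profiles, integrated iES, ln(Rsb) contrast,
empirical-tail significance and sweep-interval construction.

EHHS (site extended haplotype homozygosity) at focal marker s, extension x:
group the N haplotypes of a population by identity over all markers from s
through x inclusive, and take the unbiased homozygosity

    H(s, x) = sum_k n_k (n_k - 1) / (N (N - 1)),

normalized by the focal-site homozygosity H(s, s) (grouping by the focal
allele alone): EHHS(s, x) = H(s, x) / H(s, s). EHHS is 1 at the focal marker
and non-increasing outward, because extending the window only refines the
grouping.

iES integrates EHHS over physical position (trapezoids) in each direction,
out to the last marker with EHHS >= a truncation threshold and never across
an inter-marker gap larger than ``max_gap_bp``. ln(Rsb) = ln(iES_A / iES_B)
contrasts the two populations per SNP; after median/SD standardization,
extreme values flag SNPs where EHH decays more slowly in one population than
the other (negative values = slower decay in population B under this sign
convention). Significant SNPs are clustered into intervals (>= min_snps
members, adjacent gaps < max_gap, sign-homogeneous so each interval is
attributable to one population).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import HaplotypeSet, MarkerMap

__all__ = [
    "EhhsProfile",
    "SweepInterval",
    "ehhs_profile",
    "ies",
    "ies_scan",
    "rsb",
    "standardize_scores",
    "select_significant",
    "build_intervals",
    "scan_rsb",
    "intervals_to_bed",
]


@dataclass(frozen=True)
class EhhsProfile:
    """EHHS values at every marker of the focal chromosome (1 at the focus)."""

    focal_marker: str
    focal_index: int  # index within positions_bp
    positions_bp: np.ndarray
    ehhs: np.ndarray
    degenerate: bool = False  # focal marker monomorphic in this population


@dataclass(frozen=True)
class SweepInterval:
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    direction: str  # population label with the slower EHH decay
    peak_score: float


def _homozygosity(group_ids: np.ndarray, n: int) -> float:
    _, counts = np.unique(group_ids, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _ehhs_one_side(
    alleles: np.ndarray,
    focal: int,
    step: int,
    stop_index: int,
    h_ss: float,
    n: int,
    stop_threshold: float | None,
) -> list[float]:
    """EHHS values walking from focal+step to stop_index (inclusive) by step."""
    out: list[float] = []
    _, group = np.unique(alleles[:, focal], return_inverse=True)
    x = focal
    while x != stop_index:
        x += step
        key = group * 2 + alleles[:, x]
        _, group = np.unique(key, return_inverse=True)
        e = _homozygosity(group, n) / h_ss
        out.append(e)
        if stop_threshold is not None and e < stop_threshold:
            break
    return out


def ehhs_profile(
    h: HaplotypeSet,
    focal: int,
    stop_threshold: float | None = None,
) -> EhhsProfile:
    """EHHS at every marker of the focal marker's chromosome.

    With ``stop_threshold`` set, each direction stops early once EHHS drops
    below the threshold; since EHHS is non-increasing outward this cannot
    change any value above the threshold (used by the scan for speed).
    A monomorphic focal marker degenerates to plain haplotype homozygosity
    (single focal group) and is flagged.
    """
    n = h.n_haplotypes
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    chrom = h.markers.chrom[focal]
    on_c = np.flatnonzero(h.markers.chrom == chrom)
    alleles = h.alleles[:, on_c]
    pos = h.markers.pos_bp[on_c]
    f_local = int(np.searchsorted(on_c, focal))

    focal_col = alleles[:, f_local]
    h_ss = _homozygosity(focal_col, n)
    degenerate = len(np.unique(focal_col)) == 1
    if h_ss == 0.0:
        # all N haplotype classes distinct at the focus is impossible for a
        # biallelic marker with N >= 2 unless N == 2 and alleles differ
        h_ss = np.nan

    left = _ehhs_one_side(alleles, f_local, -1, 0, h_ss, n, stop_threshold)
    right = _ehhs_one_side(
        alleles, f_local, +1, alleles.shape[1] - 1, h_ss, n, stop_threshold
    )

    ehhs = np.full(len(on_c), np.nan)
    ehhs[f_local] = 1.0
    ehhs[f_local - len(left) : f_local] = left[::-1]
    ehhs[f_local + 1 : f_local + 1 + len(right)] = right
    return EhhsProfile(
        focal_marker=str(h.markers.ids[focal]),
        focal_index=f_local,
        positions_bp=pos,
        ehhs=ehhs,
        degenerate=degenerate,
    )


def _side_integral(
    pos: np.ndarray,
    ehhs: np.ndarray,
    focal: int,
    step: int,
    trunc_threshold: float,
    max_gap_bp: int,
) -> float:
    """Trapezoidal integral from the focal marker outward in one direction."""
    total = 0.0
    x = focal
    nxt = x + step
    while 0 <= nxt < len(pos):
        if np.isnan(ehhs[nxt]) or ehhs[nxt] < trunc_threshold:
            break
        if abs(int(pos[nxt]) - int(pos[x])) > max_gap_bp:
            break
        total += (ehhs[x] + ehhs[nxt]) / 2.0 * abs(int(pos[nxt]) - int(pos[x]))
        x = nxt
        nxt += step
    return total


def ies(
    profile: EhhsProfile,
    trunc_threshold: float = 0.05,
    max_gap_bp: int = 500_000,
) -> float:
    """Integrated EHHS (bp): trapezoids out to the last marker with
    EHHS >= ``trunc_threshold``, truncated before any gap > ``max_gap_bp``.

    A profile with a single marker has no area and returns 0 (isolated SNP).
    """
    pos, e, f = profile.positions_bp, profile.ehhs, profile.focal_index
    left = _side_integral(pos, e, f, -1, trunc_threshold, max_gap_bp)
    right = _side_integral(pos, e, f, +1, trunc_threshold, max_gap_bp)
    return left + right


def ies_scan(
    h: HaplotypeSet,
    trunc_threshold: float = 0.05,
    max_gap_bp: int = 500_000,
) -> np.ndarray:
    """iES for every marker of a (single-population) HaplotypeSet."""
    out = np.empty(len(h.markers))
    for l in range(len(h.markers)):
        prof = ehhs_profile(h, l, stop_threshold=trunc_threshold)
        out[l] = ies(prof, trunc_threshold, max_gap_bp)
    return out


def rsb(
    ies_a: np.ndarray,
    ies_b: np.ndarray,
    markers: MarkerMap,
    pop_a: str = "A",
    pop_b: str = "B",
    total_tail: float = 0.01,
    sides: str = "two",
) -> pd.DataFrame:
    """Per-SNP ln(Rsb) scan table contrasting two populations.

    ln_rsb_raw = ln(iES_A / iES_B); SNPs with zero iES in either population
    are excluded (column ``excluded_reason``). Scores are standardized
    genome-wide as (x - median) / SD, flagged by the empirical two-sided
    ``total_tail``, and labelled with the favored population: negative scores
    mean slower EHH decay in population B (B-favored).
    """
    if len(ies_a) != len(ies_b) or len(ies_a) != len(markers):
        raise ValueError("marker sets of the two populations must be identical")
    ies_a = np.asarray(ies_a, dtype=float)
    ies_b = np.asarray(ies_b, dtype=float)
    ok = (ies_a > 0) & (ies_b > 0)
    raw = np.full(len(ies_a), np.nan)
    raw[ok] = np.log(ies_a[ok] / ies_b[ok])
    std = np.full(len(ies_a), np.nan)
    flags = np.zeros(len(ies_a), dtype=bool)
    if ok.any() and np.ptp(raw[ok]) == 0.0:
        # degenerate scan (e.g. identical populations): all scores tie, so the
        # strict-inequality tail rule flags nothing
        std[ok] = 0.0
    elif ok.any():
        std[ok] = standardize_scores(raw[ok])
        flags[ok] = select_significant(std[ok], total_tail=total_tail, sides=sides)
    side = np.where(
        flags, np.where(std > 0, f"{pop_a}-favored", f"{pop_b}-favored"), "none"
    )
    reason = np.where(ok, "", "zero-iES")
    return pd.DataFrame(
        {
            "chrom": markers.chrom,
            "pos_bp": markers.pos_bp,
            "id": markers.ids,
            f"iES_{pop_a}": ies_a,
            f"iES_{pop_b}": ies_b,
            "ln_rsb_raw": raw,
            "ln_rsb_std": std,
            "significant": flags,
            "tail_side": side,
            "excluded_reason": reason,
        }
    )


def standardize_scores(raw: np.ndarray) -> np.ndarray:
    """Median-centred, SD-scaled scores: z = (raw - median) / SD."""
    raw = np.asarray(raw, dtype=float)
    finite = raw[np.isfinite(raw)]
    if len(finite) < 2:
        raise ValueError("need at least 2 finite values")
    sd = float(np.std(finite, ddof=1))
    if sd == 0.0:
        raise ValueError("zero standard deviation")
    return (raw - np.median(finite)) / sd


def select_significant(
    scores: np.ndarray, total_tail: float = 0.01, sides: str = "two"
) -> np.ndarray:
    """Empirical-tail flags: total tail mass ``total_tail``, split across both
    tails by default; ties at the cutoffs are excluded (strict inequality).
    """
    if not (0.0 < total_tail < 1.0):
        raise ValueError("total_tail must be in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    srt = np.sort(scores)
    n = len(srt)

    def lower_cut(p: float) -> float:
        # cutoff so that exactly floor(p*n) distinct scores fall strictly below
        k = int(np.floor(p * n))
        return srt[min(k, n - 1)]

    def upper_cut(p: float) -> float:
        k = int(np.floor(p * n))
        return srt[max(n - 1 - k, 0)]

    if sides == "two":
        return (scores < lower_cut(total_tail / 2.0)) | (
            scores > upper_cut(total_tail / 2.0)
        )
    if sides == "lower":
        return scores < lower_cut(total_tail)
    if sides == "upper":
        return scores > upper_cut(total_tail)
    raise ValueError("sides must be 'two', 'lower' or 'upper'")


def build_intervals(
    flags: np.ndarray,
    scores: np.ndarray,
    markers: MarkerMap,
    pop_a: str = "A",
    pop_b: str = "B",
    max_gap_bp: int = 1_000_000,
    min_snps: int = 2,
) -> list[SweepInterval]:
    """Cluster significant SNPs into sign-homogeneous genomic intervals.

    On each chromosome, consecutive significant SNPs join one cluster while
    the gap to the previous member is < ``max_gap_bp`` and the score sign is
    unchanged; clusters with >= ``min_snps`` members become intervals spanning
    [first member, last member]. Direction: positive mean score -> slower
    decay in population A (A-favored); negative -> B-favored.
    """
    flags = np.asarray(flags, dtype=bool)
    out: list[SweepInterval] = []
    for chrom in pd.unique(markers.chrom):
        on_c = np.flatnonzero((markers.chrom == chrom) & flags)
        if len(on_c) == 0:
            continue
        pos = markers.pos_bp[on_c]
        z = np.asarray(scores, dtype=float)[on_c]
        cluster: list[int] = []

        def emit(members: list[int]) -> None:
            if len(members) < min_snps:
                return
            mz = z[members]
            out.append(
                SweepInterval(
                    chrom=str(chrom),
                    start_bp=int(pos[members[0]]),
                    end_bp=int(pos[members[-1]]),
                    n_snps=len(members),
                    direction=pop_a if mz.mean() > 0 else pop_b,
                    peak_score=float(mz[np.argmax(np.abs(mz))]),
                )
            )

        for k in range(len(on_c)):
            if not cluster:
                cluster = [k]
                continue
            prev = cluster[-1]
            same_sign = (z[k] > 0) == (z[prev] > 0)
            if pos[k] - pos[prev] < max_gap_bp and same_sign:
                cluster.append(k)
            else:
                emit(cluster)
                cluster = [k]
        emit(cluster)
    return out


def scan_rsb(
    h: HaplotypeSet,
    pop_a: str,
    pop_b: str,
    trunc_threshold: float = 0.05,
    max_gap_bp: int = 500_000,
    total_tail: float = 0.01,
    sides: str = "two",
    interval_max_gap_bp: int = 1_000_000,
    min_snps: int = 2,
) -> tuple[pd.DataFrame, list[SweepInterval]]:
    """Full two-population scan: per-SNP iES in each population, ln(Rsb)
    standardization and flags, and clustered sweep intervals.
    """
    ies_a = ies_scan(h.restrict_population(pop_a), trunc_threshold, max_gap_bp)
    ies_b = ies_scan(h.restrict_population(pop_b), trunc_threshold, max_gap_bp)
    table = rsb(ies_a, ies_b, h.markers, pop_a, pop_b, total_tail, sides)
    intervals = build_intervals(
        table["significant"].to_numpy(),
        table["ln_rsb_std"].to_numpy(),
        h.markers,
        pop_a,
        pop_b,
        max_gap_bp=interval_max_gap_bp,
        min_snps=min_snps,
    )
    return table, intervals


def intervals_to_bed(intervals: list[SweepInterval], path: str) -> None:
    """Write intervals as BED (0-based half-open; name=direction, score=peak)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start_bp - 1}\t{iv.end_bp}\t"
                f"{iv.direction}\t{iv.peak_score:.4f}\t.\n"
            )
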