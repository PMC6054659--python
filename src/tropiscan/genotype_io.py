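"""Reading/writing PLINK text and phased VCF, QC filtering and LD pruning.

The PED dialect follows PLINK's text layout: six leading columns
(FID IID PAT MAT SEX PHENO) then two allele columns per marker; "0" denotes a
missing allele. The family id (FID) column doubles as the population label,
which is how breed labels are normally carried in these files.

Allele orientation for PED input: with no declared reference, ``allele_alt``
is the lexicographically later of the two observed alleles unless an explicit
override is supplied. All downstream statistics (Fst, r2, EHHS) are invariant
under swapping ref/alt, so the choice only fixes the sign convention of the
dosage encoding.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    DataError,
    FormatError,
    GenotypeMatrix,
    HaplotypeSet,
    MarkerMap,
    SampleTable,
)

__all__ = [
    "read_plink_text",
    "write_plink_text",
    "read_phased_vcf",
    "write_phased_vcf",
    "qc_filter",
    "ld_prune",
]


def _read_map(map_path: str | os.PathLike) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            map_path,
            sep=r"\s+",
            header=None,
            names=["chrom", "id", "cm", "pos_bp"],
            dtype={"chrom": str, "id": str},
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty MAP file: {map_path}") from None
    if df.shape[1] != 4 or df["pos_bp"].isna().any():
        raise FormatError(f"MAP file {map_path} must have 4 columns (chrom id cM bp)")
    return df


def read_plink_text(
    ped_path: str | os.PathLike,
    map_path: str | os.PathLike,
    alt_alleles: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Read a PLINK text PED/MAP pair into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    alt_alleles
        Optional ``{marker_id: allele}`` override of the counted (alt) allele;
        by default the lexicographically later observed allele is counted.
    """
    map_df = _read_map(map_path)
    n_markers = len(map_df)

    fids, iids = [], []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_markers:
                raise FormatError(
                    f"PED line {line_no}: expected {6 + 2 * n_markers} columns "
                    f"(6 + 2 x {n_markers} markers), got {len(fields)}"
                )
            fids.append(fields[0])
            iids.append(fields[1])
            allele_rows.append(fields[6:])
    if not allele_rows:
        raise FormatError(f"PED file {ped_path} contains no individuals")

    alleles = np.asarray(allele_rows, dtype=object).reshape(len(allele_rows), n_markers, 2)

    ref = np.empty(n_markers, dtype=object)
    alt = np.empty(n_markers, dtype=object)
    dosage = np.full((len(allele_rows), n_markers), MISSING, dtype=np.int8)
    for l in range(n_markers):
        col = alleles[:, l, :]
        called = col != "0"
        # half-missing calls ("A 0") are treated as fully missing
        both = called.all(axis=1)
        observed = sorted(set(col[called]))
        if len(observed) > 2:
            raise DataError(
                f"locus {map_df['id'].iloc[l]!r} has >2 alleles: {observed}"
            )
        if not observed:
            ref[l], alt[l] = "0", "0"
            continue
        if len(observed) == 1:
            # monomorphic among calls: observed allele is ref, alt unseen
            observed = [observed[0], "."]
        a_ref, a_alt = observed
        marker_id = str(map_df["id"].iloc[l])
        if alt_alleles and marker_id in alt_alleles:
            forced = alt_alleles[marker_id]
            if forced not in (a_ref, a_alt):
                raise DataError(
                    f"override alt allele {forced!r} not observed at {marker_id!r}"
                )
            if forced == a_ref:
                a_ref, a_alt = a_alt, a_ref
        ref[l], alt[l] = a_ref, a_alt
        counts = (col == a_alt).sum(axis=1).astype(np.int8)
        dosage[both, l] = counts[both]

    markers = MarkerMap(
        chrom=map_df["chrom"].to_numpy(dtype=object),
        pos_bp=map_df["pos_bp"].to_numpy(dtype=np.int64),
        ids=map_df["id"].to_numpy(dtype=object),
        allele_ref=ref,
        allele_alt=alt,
    )
    samples = SampleTable(
        ids=np.asarray(iids, dtype=object), populations=np.asarray(fids, dtype=object)
    )
    return GenotypeMatrix(samples=samples, markers=markers, dosage=dosage)


def write_plink_text(g: GenotypeMatrix, ped_path: str, map_path: str) -> None:
    """Write PED/MAP; FID = population label, cM column written as 0."""
    with open(map_path, "w") as fh:
        for c, i, p in zip(g.markers.chrom, g.markers.ids, g.markers.pos_bp):
            fh.write(f"{c}\t{i}\t0\t{p}\n")
    ref, alt = g.markers.allele_ref, g.markers.allele_alt
    with open(ped_path, "w") as fh:
        for s in range(g.n_samples):
            fields = [
                str(g.samples.populations[s]),
                str(g.samples.ids[s]),
                "0",
                "0",
                "0",
                "-9",
            ]
            row = g.dosage[s]
            for l in range(g.n_markers):
                d = row[l]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [str(ref[l]), str(ref[l])]
                elif d == 1:
                    fields += [str(ref[l]), str(alt[l])]
                else:
                    fields += [str(alt[l]), str(alt[l])]
            fh.write(" ".join(fields) + "\n")


def read_phased_vcf(
    vcf_path: str | os.PathLike,
    populations: Mapping[str, str] | None = None,
) -> HaplotypeSet:
    """Read a phased, biallelic VCF into a :class:`HaplotypeSet`.

    All GT fields must be phased ("|") and complete: the EHH statistics this
    container feeds require full haplotypes. ``populations`` maps sample id to
    population label (default: single population "pop").
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    sample_ids = np.asarray(vcf.samples, dtype=object)
    n = len(sample_ids)

    chroms, poss, ids, refs, alts = [], [], [], [], []
    rows: list[np.ndarray] = []
    for k, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            raise DataError(f"record {rec.CHROM}:{rec.POS} is not biallelic")
        gts = rec.genotypes  # [allele_a, allele_b, phased] per sample
        col = np.empty(2 * n, dtype=np.int8)
        for i, gt in enumerate(gts):
            a, b, phased = gt[0], gt[1], gt[-1]
            if a < 0 or b < 0:
                raise DataError(
                    f"missing GT at {rec.CHROM}:{rec.POS} sample {sample_ids[i]}: "
                    "EHH analyses require complete haplotypes"
                )
            if not phased:
                raise DataError(
                    f"unphased GT at {rec.CHROM}:{rec.POS} sample {sample_ids[i]}: "
                    "phase the data (e.g. with Beagle/SHAPEIT) before EHH analysis"
                )
            col[2 * i], col[2 * i + 1] = a, b
        rows.append(col)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        ids.append(rec.ID if rec.ID is not None else f"{rec.CHROM}:{rec.POS}")
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
    if not rows:
        raise FormatError(f"VCF {vcf_path} contains no records")

    markers = MarkerMap(
        chrom=np.asarray(chroms, dtype=object),
        pos_bp=np.asarray(poss, dtype=np.int64),
        ids=np.asarray(ids, dtype=object),
        allele_ref=np.asarray(refs, dtype=object),
        allele_alt=np.asarray(alts, dtype=object),
    )
    sample_of_hap = np.repeat(sample_ids, 2)
    if populations is None:
        pops = np.asarray(["pop"] * 2 * n, dtype=object)
    else:
        pops = np.asarray([populations[str(s)] for s in sample_of_hap], dtype=object)
    return HaplotypeSet(
        markers=markers,
        sample_of_haplotype=sample_of_hap,
        alleles=np.vstack(rows).T.astype(np.int8),
        populations=pops,
    )


def write_phased_vcf(h: HaplotypeSet, path: str) -> None:
    """Write a minimal phased VCF 4.2 (GT only, deterministic header)."""
    ids = h.sample_of_haplotype[0::2]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(h.markers.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(i) for i in ids)
            + "\n"
        )
        left, right = h.alleles[0::2, :], h.alleles[1::2, :]
        m = h.markers
        for l in range(len(m)):
            gts = "\t".join(
                f"{a}|{b}" for a, b in zip(left[:, l], right[:, l])
            )
            fh.write(
                f"{m.chrom[l]}\t{m.pos_bp[l]}\t{m.ids[l]}\t{m.allele_ref[l]}\t"
                f"{m.allele_alt[l]}\t.\t.\t.\tGT\t{gts}\n"
            )


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    miss_max: float = 0.01,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop loci with MAF below ``maf_min`` or missing fraction above ``miss_max``.

    MAF is computed from non-missing calls only. Returns the filtered matrix
    and a removal report with one row per removed locus (id, reason); a locus
    failing several rules lists all reasons separated by ";".
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    if not (0.0 <= miss_max <= 1.0):
        raise ValueError("miss_max must be in [0, 1]")

    maf = g.maf()
    miss = g.missing_fraction()
    all_missing = np.isnan(maf)
    low_maf = ~all_missing & (maf < maf_min)
    high_miss = miss > miss_max

    removed = all_missing | low_maf | high_miss
    reasons = []
    for l in np.flatnonzero(removed):
        r = []
        if all_missing[l]:
            r.append("all-missing")
        if low_maf[l]:
            r.append(f"maf<{maf_min:g}")
        if high_miss[l]:
            r.append(f"missing>{miss_max:g}")
        reasons.append(";".join(r))
    report = pd.DataFrame(
        {"id": g.markers.ids[removed], "reason": reasons}
    )
    return g.subset_markers(np.flatnonzero(~removed)), report


def ld_prune(
    g: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.5,
) -> GenotypeMatrix:
    """Greedy sliding-window LD pruning (PLINK ``--indep-pairwise`` style).

    Within each window of ``window_snps`` retained loci, while any pair has
    EM-estimated r2 above ``r2_max`` the member with the lower MAF is removed
    (on a tie, the later map position); the window then advances by
    ``step_snps``. Deterministic for a fixed input.
    """
    from .linkage import r2_unphased_em

    if not (window_snps > step_snps > 0):
        raise ValueError("require window_snps > step_snps > 0")

    maf = g.maf()
    keep = np.ones(g.n_markers, dtype=bool)
    cache: dict[tuple[int, int], float] = {}

    def pair_r2(i: int, j: int) -> float:
        key = (i, j)
        if key not in cache:
            r2 = r2_unphased_em(g, i, j)
            cache[key] = 0.0 if np.isnan(r2) else r2
        return cache[key]

    start = 0
    while start < g.n_markers:
        window = [l for l in range(start, min(start + window_snps, g.n_markers)) if keep[l]]
        changed = True
        while changed:
            changed = False
            for a in range(len(window)):
                i = window[a]
                if not keep[i]:
                    continue
                for b in range(a + 1, len(window)):
                    j = window[b]
                    if not keep[j]:
                        continue
                    if pair_r2(i, j) > r2_max:
                        # victim: lower MAF; tie -> later map position (j)
                        victim = i if maf[i] < maf[j] else j
                        keep[victim] = False
                        changed = True
                        break
                if changed:
                    break
        start += step_snps
    return g.subset_markers(np.flatnonzero(keep))
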