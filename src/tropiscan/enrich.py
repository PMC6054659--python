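"""Interval-to-gene mapping and gene-set over-representation testing.

Over-representation uses the one-sided hypergeometric (Fisher) tail: with a
universe of N genes of which K belong to a set, and a candidate list of n
genes of which k are in the set, p = P(X >= k) for X ~ Hypergeom(N, K, n).
P-values are adjusted with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .sweepscan import SweepInterval

__all__ = [
    "read_bed_genes",
    "read_gff3_genes",
    "read_gmt",
    "intervals_to_genes",
    "fisher_enrichment",
    "bh_adjust",
]


def read_bed_genes(path: str) -> pd.DataFrame:
    """Gene annotation from BED (chrom, start, end, name[, score, strand]).

    BED coordinates are 0-based half-open; they are converted to the package's
    1-based inclusive convention.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("BED gene annotation needs at least 4 columns")
    out = pd.DataFrame(
        {
            "gene_id": df[3].astype(str),
            "chrom": df[0].astype(str),
            "start_bp": df[1].astype(int) + 1,
            "end_bp": df[2].astype(int),
            "strand": df[5].astype(str) if df.shape[1] > 5 else ".",
        }
    )
    return out


_GFF_ID = re.compile(r"(?:^|;)\s*(?:ID|gene_id|Name)=([^;]+)")


def read_gff3_genes(path: str, feature_type: str = "gene") -> pd.DataFrame:
    """Gene records from a GFF3 file (1-based inclusive, as GFF3 itself)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=[
            "chrom",
            "source",
            "type",
            "start",
            "end",
            "score",
            "strand",
            "phase",
            "attributes",
        ],
        dtype={"chrom": str},
    )
    genes = df[df["type"] == feature_type]
    ids = []
    for attr in genes["attributes"]:
        m = _GFF_ID.search(str(attr))
        ids.append(m.group(1) if m else str(attr))
    return pd.DataFrame(
        {
            "gene_id": ids,
            "chrom": genes["chrom"].to_numpy(),
            "start_bp": genes["start"].to_numpy(dtype=int),
            "end_bp": genes["end"].to_numpy(dtype=int),
            "strand": genes["strand"].to_numpy(),
        }
    )


def read_gmt(path: str) -> dict[str, set[str]]:
    """GMT gene sets: one set per line (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def intervals_to_genes(
    intervals: list[SweepInterval] | pd.DataFrame,
    annotation: pd.DataFrame,
    flank_bp: int = 0,
) -> pd.DataFrame:
    """Genes whose flank-extended span overlaps any interval by >= 1 bp.

    Returns a de-duplicated table (gene_id, chrom, start_bp, end_bp) with a
    ``intervals`` column recording the overlapping interval ids
    ("chrom:start-end", comma-joined). Warns when intervals name chromosomes
    absent from the annotation.
    """
    import warnings

    if isinstance(intervals, list):
        iv = pd.DataFrame(
            {
                "chrom": [i.chrom for i in intervals],
                "start_bp": [i.start_bp for i in intervals],
                "end_bp": [i.end_bp for i in intervals],
            }
        )
    else:
        iv = intervals[["chrom", "start_bp", "end_bp"]].copy()

    known = set(annotation["chrom"].astype(str))
    missing = [c for c in iv["chrom"].astype(str) if c not in known]
    if missing:
        warnings.warn(
            f"{len(missing)} interval(s) on chromosomes absent from the annotation",
            UserWarning,
            stacklevel=2,
        )

    hits: dict[str, dict] = {}
    for _, row in iv.iterrows():
        on_c = annotation[annotation["chrom"].astype(str) == str(row["chrom"])]
        g_start = on_c["start_bp"].to_numpy() - flank_bp
        g_end = on_c["end_bp"].to_numpy() + flank_bp
        overlap = (g_start <= row["end_bp"]) & (g_end >= row["start_bp"])
        label = f"{row['chrom']}:{row['start_bp']}-{row['end_bp']}"
        for _, gene in on_c[overlap].iterrows():
            gid = str(gene["gene_id"])
            if gid not in hits:
                hits[gid] = {
                    "gene_id": gid,
                    "chrom": gene["chrom"],
                    "start_bp": gene["start_bp"],
                    "end_bp": gene["end_bp"],
                    "intervals": [label],
                }
            else:
                hits[gid]["intervals"].append(label)
    rows = list(hits.values())
    for r in rows:
        r["intervals"] = ",".join(r["intervals"])
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start_bp", "end_bp", "intervals"]
    )


def fisher_enrichment(
    gene_list: set[str] | list[str],
    universe: set[str] | list[str],
    gene_sets: dict[str, set[str]],
    adjust: bool = True,
) -> pd.DataFrame:
    """One-sided over-representation test of ``gene_list`` against each set.

    Sets are intersected with the universe before testing; sets disjoint from
    the universe are skipped (recorded with ``skipped_reason``). Rows are
    sorted by raw p-value.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    gene_list = set(gene_list)
    if not gene_list <= universe:
        extra = sorted(gene_list - universe)[:5]
        raise ValueError(f"gene list is not a subset of the universe (e.g. {extra})")
    n_univ = len(universe)
    n_list = len(gene_list)

    rows = []
    for set_id, members in gene_sets.items():
        in_univ = members & universe
        if not in_univ:
            rows.append(
                {
                    "set_id": set_id,
                    "k": 0,
                    "K": 0,
                    "n": n_list,
                    "N": n_univ,
                    "p_raw": np.nan,
                    "skipped_reason": "disjoint-from-universe",
                }
            )
            continue
        k = len(gene_list & in_univ)
        big_k = len(in_univ)
        p = float(hypergeom.sf(k - 1, n_univ, big_k, n_list))
        rows.append(
            {
                "set_id": set_id,
                "k": k,
                "K": big_k,
                "n": n_list,
                "N": n_univ,
                "p_raw": min(p, 1.0),
                "skipped_reason": "",
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values("p_raw", na_position="last", kind="mergesort").reset_index(
            drop=True
        )
        if adjust:
            tested = df["p_raw"].notna()
            adj = np.full(len(df), np.nan)
            if tested.any():
                adj[tested.to_numpy()] = bh_adjust(df.loc[tested, "p_raw"].to_numpy())
            df["p_adj"] = adj
    return df


def bh_adjust(p_raw: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_raw, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
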