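"""End-to-end orchestration: simulate -> qc -> fst -> ld -> scan -> structure
-> enrich, driven by one structured config, with a checksummed manifest.

Stages communicate only through declared file artifacts in the output
directory, so the pipeline can be re-run from any midpoint. All randomness
derives from the single config seed; outputs are byte-identical across runs
of the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import diversity, enrich, genotype_io, linkage, simdata, structure, sweepscan

log = logging.getLogger("tropiscan")

#: Per-stage parameter defaults; every key can be overridden from the config.
DEFAULTS: dict[str, dict[str, Any]] = {
    "qc": {"maf_min": 0.01, "miss_max": 0.01},
    "fst": {"permute": None, "n_perm": 1000},
    "ld": {"max_dist_bp": 1_000_000, "bin_width_bp": 10_000},
    "scan": {
        "pop_a": "A",
        "pop_b": "B",
        "trunc_threshold": 0.05,
        "max_gap_bp": 500_000,
        "total_tail": 0.01,
        "sides": "two",
        "interval_max_gap_bp": 1_000_000,
        "min_snps": 2,
    },
    "structure": {"n_components": 10, "tree_level": "individuals", "n_boot": 100},
    "enrich": {"flank_bp": 0, "alpha": 0.05, "annotation": None, "gmt": None},
}


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _merge(stage: str, config: dict) -> dict:
    params = dict(DEFAULTS[stage])
    params.update(config.get(stage) or {})
    return params


def synthetic_gene_annotation(
    chrom: str, chrom_length_bp: int, n_genes: int, seed: int
) -> pd.DataFrame:
    """Synthetic gene annotation: ~20 kb genes tiled at random positions.

    A stand-in for a real genome annotation, for demo/benchmark runs only.
    """
    rng = np.random.default_rng(seed)
    starts = np.sort(rng.integers(1, chrom_length_bp - 20_000, size=n_genes))
    return pd.DataFrame(
        {
            "gene_id": [f"GENE{k:04d}" for k in range(n_genes)],
            "chrom": chrom,
            "start_bp": starts,
            "end_bp": starts + rng.integers(5_000, 20_000, size=n_genes),
            "strand": rng.choice(["+", "-"], size=n_genes),
        }
    )


def synthetic_gene_sets(
    gene_ids: list[str], n_sets: int, seed: int, mean_size: int = 25
) -> dict[str, set[str]]:
    """Synthetic GMT-style gene sets drawn uniformly from the gene universe."""
    rng = np.random.default_rng(seed)
    sets = {}
    for k in range(n_sets):
        size = max(3, int(rng.poisson(mean_size)))
        members = rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False)
        sets[f"SET{k:03d}"] = set(str(m) for m in members)
    return sets


def _write_gmt(sets: dict[str, set[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, "synthetic"] + sorted(sets[name])) + "\n")


def run_pipeline(config: dict, outdir: str) -> dict:
    """Run every configured stage in dependency order; return the manifest."""
    os.makedirs(outdir, exist_ok=True)
    seed = int(config.get("seed", 0))
    artifacts: dict[str, str] = {}
    counts: dict[str, Any] = {}

    def declare(name: str) -> str:
        return os.path.join(outdir, name)

    def record(name: str) -> None:
        artifacts[name] = _sha256(declare(name))

    # validate all stage parameter blocks up front, then echo the config
    for stage in DEFAULTS:
        params = _merge(stage, config)
        unknown = set(params) - set(DEFAULTS[stage])
        if unknown:
            raise ValueError(f"unknown {stage} parameters: {sorted(unknown)}")
    with open(declare("config.yaml"), "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    record("config.yaml")

    # --- simulate ---------------------------------------------------------
    stage = "simulate"
    try:
        if "simulate" in config:
            sim = dict(config["simulate"])
            sweep = sim.pop("sweep", None)
            if sweep is not None:
                sweep = simdata.SweepSpec(**sweep)
            cfg = simdata.SimulationConfig(seed=seed, sweep=sweep, **sim)
            hap, geno, truth = simdata.simulate_dataset(cfg)
            log.info(
                "simulate: %d pops x %d diploids, %d markers",
                cfg.n_pops,
                cfg.n_individuals,
                cfg.n_markers,
            )
            genotype_io.write_phased_vcf(hap, declare("phased.vcf"))
            genotype_io.write_plink_text(
                geno, declare("genotypes.ped"), declare("genotypes.map")
            )
            pd.DataFrame(
                {
                    "id": geno.samples.ids,
                    "population": geno.samples.populations,
                }
            ).to_csv(declare("samples.tsv"), sep="\t", index=False)
            with open(declare("truth.json"), "w") as fh:
                json.dump(truth, fh, indent=2, sort_keys=True)
            for name in ("phased.vcf", "genotypes.ped", "genotypes.map",
                         "samples.tsv", "truth.json"):
                record(name)
            if "sweep" in truth:
                t = truth["sweep"]
                with open(declare("truth_sweep.bed"), "w") as fh:
                    fh.write(
                        f"{t['chrom']}\t{t['start_bp'] - 1}\t{t['end_bp']}\t"
                        f"{t['pop']}\t.\t.\n"
                    )
                record("truth_sweep.bed")
            ped, map_ = declare("genotypes.ped"), declare("genotypes.map")
            vcf = declare("phased.vcf")
            samples_tsv = declare("samples.tsv")
        else:
            inputs = config.get("inputs", {})
            ped, map_ = inputs.get("ped"), inputs.get("map")
            vcf = inputs.get("vcf")
            samples_tsv = inputs.get("samples")
            if not (ped and map_):
                raise ValueError("config needs a 'simulate' block or inputs.ped/map")

        # --- qc -----------------------------------------------------------
        stage = "qc"
        params = _merge("qc", config)
        g = genotype_io.read_plink_text(ped, map_)
        counts["markers_in"] = g.n_markers
        g_qc, report = genotype_io.qc_filter(g, **params)
        counts["markers_after_qc"] = g_qc.n_markers
        log.info("qc: %d markers in, %d retained", g.n_markers, g_qc.n_markers)
        report.to_csv(declare("qc_removed.tsv"), sep="\t", index=False)
        genotype_io.write_plink_text(
            g_qc, declare("qc.ped"), declare("qc.map")
        )
        for name in ("qc_removed.tsv", "qc.ped", "qc.map"):
            record(name)

        # --- fst ----------------------------------------------------------
        stage = "fst"
        params = _merge("fst", config)
        g_qc = genotype_io.read_plink_text(declare("qc.ped"), declare("qc.map"))
        mat = diversity.pairwise_fst_matrix(g_qc)
        mat.to_csv(declare("fst_matrix.tsv"), sep="\t")
        record("fst_matrix.tsv")
        permute = params["permute"]
        if permute is None:
            pops = list(pd.unique(g_qc.samples.populations))
            permute = pops[:2] if len(pops) >= 2 else None
        if permute:
            res = diversity.fst_permutation_test(
                g_qc, permute[0], permute[1], n_perm=params["n_perm"], seed=seed
            )
            pd.DataFrame({"null_theta": res.null_thetas}).to_csv(
                declare("fst_null.tsv"), sep="\t", index=False
            )
            record("fst_null.tsv")
            counts["fst_observed"] = res.observed_theta
            counts["fst_p_value"] = res.p_value
            log.info(
                "fst: observed theta=%.4f p=%.4g (%d permutations)",
                res.observed_theta,
                res.p_value,
                params["n_perm"],
            )

        # --- ld -----------------------------------------------------------
        stage = "ld"
        if vcf:
            params = _merge("ld", config)
            pops_map = _read_samples_tsv(samples_tsv)
            hap = genotype_io.read_phased_vcf(vcf, populations=pops_map)
            profile = linkage.ld_decay_profile(hap, **params)
            profile.to_tsv(declare("ld_decay.tsv"))
            record("ld_decay.tsv")

            # --- scan -----------------------------------------------------
            stage = "scan"
            params = _merge("scan", config)
            table, intervals = sweepscan.scan_rsb(hap, **params)
            counts["snps_flagged"] = int(table["significant"].sum())
            counts["intervals"] = len(intervals)
            log.info(
                "scan: %d SNPs flagged, %d intervals",
                counts["snps_flagged"],
                counts["intervals"],
            )
            table.to_csv(declare("scan.tsv"), sep="\t", index=False)
            sweepscan.intervals_to_bed(intervals, declare("intervals.bed"))
            record("scan.tsv")
            record("intervals.bed")

        # --- structure ----------------------------------------------------
        stage = "structure"
        params = _merge("structure", config)
        res = structure.pca(g_qc, n_components=params["n_components"])
        res.to_dataframe().to_csv(declare("pca.tsv"), sep="\t", index=False)
        pd.DataFrame({"eigenvalue": res.eigenvalues}).to_csv(
            declare("pca_eigenvalues.tsv"), sep="\t", index=False
        )
        tree = structure.bootstrap_support(
            g_qc, level=params["tree_level"], n_boot=params["n_boot"], seed=seed
        )
        with open(declare("tree.nwk"), "w") as fh:
            fh.write(tree.to_newick() + "\n")
        for name in ("pca.tsv", "pca_eigenvalues.tsv", "tree.nwk"):
            record(name)

        # --- enrich -------------------------------------------------------
        stage = "enrich"
        params = _merge("enrich", config)
        if os.path.exists(declare("intervals.bed")):
            ann_path, gmt_path = params["annotation"], params["gmt"]
            if ann_path is None:
                chrom_len = int(
                    config.get("simulate", {}).get("chrom_length_bp", 120_000_000)
                )
                chrom = str(config.get("simulate", {}).get("chrom", "1"))
                ann = synthetic_gene_annotation(chrom, chrom_len, 400, seed)
                ann_path = declare("synthetic_genes.tsv")
                ann.to_csv(ann_path, sep="\t", index=False)
                record("synthetic_genes.tsv")
            else:
                ann = (
                    enrich.read_gff3_genes(ann_path)
                    if str(ann_path).endswith((".gff", ".gff3"))
                    else enrich.read_bed_genes(ann_path)
                )
            if gmt_path is None:
                sets = synthetic_gene_sets(list(ann["gene_id"]), 50, seed + 1)
                gmt_path = declare("synthetic_sets.gmt")
                _write_gmt(sets, gmt_path)
                record("synthetic_sets.gmt")
            else:
                sets = enrich.read_gmt(gmt_path)
            bed = pd.read_csv(
                declare("intervals.bed"), sep="\t", header=None,
                names=["chrom", "start0", "end", "name", "score", "strand"],
                dtype={"chrom": str},
            )
            iv = pd.DataFrame(
                {
                    "chrom": bed["chrom"],
                    "start_bp": bed["start0"] + 1,
                    "end_bp": bed["end"],
                }
            )
            genes = enrich.intervals_to_genes(iv, ann, flank_bp=params["flank_bp"])
            genes.to_csv(declare("sweep_genes.tsv"), sep="\t", index=False)
            record("sweep_genes.tsv")
            counts["sweep_genes"] = len(genes)
            universe = set(ann["gene_id"].astype(str))
            if len(genes):
                table = enrich.fisher_enrichment(
                    set(genes["gene_id"].astype(str)), universe, sets
                )
                table.to_csv(declare("enrichment.tsv"), sep="\t", index=False)
                record("enrichment.tsv")
    except Exception as exc:
        manifest = {"stages_completed": stage, "artifacts": artifacts, "counts": counts}
        with open(declare("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {"artifacts": artifacts, "counts": counts}
    with open(declare("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _read_samples_tsv(path: str | None) -> dict[str, str] | None:
    if path is None:
        return None
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["id"], df["population"]))


def load_config(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
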