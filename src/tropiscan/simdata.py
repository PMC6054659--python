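"""Synthetic multi-population phased haplotypes with controlled differentiation,
chip-like LD decay and an optional injected selective sweep.

Model
-----
Differentiation: per-locus ancestral frequencies p_l ~ Uniform(0.05, 0.95);
each population draws its own frequency from the Balding-Nichols beta,

    p_il ~ Beta(p_l (1 - F) / F,  (1 - p_l)(1 - F) / F),

so that the expected Fst between populations equals the target F.

LD: each population receives ``n_founders`` founder haplotypes drawn site-wise
Bernoulli(p_il). Every sample haplotype is a mosaic that starts on a random
founder and, across each inter-marker gap of d bp, switches to a uniformly
chosen founder with probability 1 - exp(-rho d). Correlation between nearby
markers therefore decays with physical distance on the scale 1/rho.

Sweep: a fraction f of one population's haplotypes (the "carriers") have their
alleles within core_length_bp/2 of a focal marker overwritten by a single
donor haplotype (founder 0 of that population), producing the long shared
haplotypes that an EHH-based scan should detect.

Note that the founder bottleneck adds drift of order 1/n_founders on top of
the Balding-Nichols target, so realized Fst between mosaic populations
exceeds F. Where Fst itself is the quantity under study, use
:func:`simulate_genotypes`, which samples alleles independently per haplotype
(the n_founders -> infinity limit) and recovers F without that bias.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .datamodel import (
    MISSING,
    GenotypeMatrix,
    HaplotypeSet,
    MarkerMap,
    SampleTable,
)

__all__ = [
    "SweepSpec",
    "SimulationConfig",
    "sample_balding_nichols_freqs",
    "simulate_mosaic_haplotypes",
    "simulate_genotypes",
    "inject_sweep",
    "haplotypes_to_genotypes",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SweepSpec:
    """A localized selective sweep injected into one population."""

    pop: str
    focal_marker_index: int
    core_length_bp: int = 1_000_000
    carrier_freq: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.carrier_freq <= 1.0):
            raise ValueError("carrier_freq must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Two-(or more-)population simulation parameters.

    Defaults emulate a 50K-chip single-chromosome panel: ~60 kb mean marker
    spacing, switch rate rho = 5e-6 per bp (LD decay scale ~100 kb), target
    Fst = 0.05 (the differentiation regime of two recently separated breed
    populations), 40 diploids per population.
    """

    n_pops: int = 2
    n_individuals: int = 40
    n_markers: int = 2000
    chrom_length_bp: int = 120_000_000
    target_fst: float = 0.05
    n_founders: int = 20
    switch_rate: float = 5e-6
    missing_rate: float = 0.0
    sweep: SweepSpec | None = None
    seed: int = 0
    chrom: str = "1"

    def __post_init__(self) -> None:
        if min(self.n_pops, self.n_individuals, self.n_markers, self.n_founders) <= 0:
            raise ValueError("all counts must be positive")
        if not (0.0 < self.target_fst < 1.0):
            raise ValueError("target_fst must be in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def pop_labels(self) -> list[str]:
        return [chr(ord("A") + k) for k in range(self.n_pops)]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


def _draw_marker_map(cfg: SimulationConfig, rng: np.random.Generator) -> MarkerMap:
    pos = np.sort(
        rng.choice(np.int64(cfg.chrom_length_bp), size=cfg.n_markers, replace=False)
    ).astype(np.int64) + 1
    n = cfg.n_markers
    return MarkerMap(
        chrom=np.asarray([cfg.chrom] * n, dtype=object),
        pos_bp=pos,
        ids=np.asarray([f"snp{k}" for k in range(n)], dtype=object),
        allele_ref=np.asarray(["A"] * n, dtype=object),
        allele_alt=np.asarray(["G"] * n, dtype=object),
    )


def sample_balding_nichols_freqs(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Per-population allele-frequency matrix (n_pops x n_markers)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    f = cfg.target_fst
    p_anc = rng.uniform(0.05, 0.95, size=cfg.n_markers)
    alpha = p_anc * (1 - f) / f
    beta = (1 - p_anc) * (1 - f) / f
    return rng.beta(alpha, beta, size=(cfg.n_pops, cfg.n_markers))


def simulate_mosaic_haplotypes(
    freqs: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    markers: MarkerMap | None = None,
) -> HaplotypeSet:
    """Founder-mosaic haplotypes for every population, as one HaplotypeSet.

    Founder haplotypes (per population) are drawn site-wise Bernoulli(p_il);
    each of the 2 x n_individuals sample haplotypes copies a random founder
    and at each inter-marker gap of d bp switches to a uniformly chosen
    founder with probability 1 - exp(-rho d).
    """
    if cfg.n_founders < 2:
        raise ValueError("n_founders must be >= 2")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if markers is None:
        markers = _draw_marker_map(cfg, rng)
    n_m = len(markers)
    if freqs.shape != (cfg.n_pops, n_m):
        raise ValueError("freqs shape must be (n_pops, n_markers)")

    gaps = np.diff(markers.pos_bp).astype(float)
    p_switch = 1.0 - np.exp(-cfg.switch_rate * gaps)

    all_alleles = []
    sample_ids = []
    pop_of_hap = []
    founders_by_pop: dict[str, np.ndarray] = {}
    n_h = 2 * cfg.n_individuals
    for k, label in enumerate(cfg.pop_labels):
        founders = (rng.random((cfg.n_founders, n_m)) < freqs[k]).astype(np.int8)
        founders_by_pop[label] = founders

        idx = np.empty((n_h, n_m), dtype=np.int32)
        idx[:, 0] = rng.integers(cfg.n_founders, size=n_h)
        switch = rng.random((n_h, n_m - 1)) < p_switch[None, :]
        new_f = rng.integers(cfg.n_founders, size=(n_h, n_m - 1))
        for l in range(1, n_m):
            idx[:, l] = np.where(switch[:, l - 1], new_f[:, l - 1], idx[:, l - 1])
        all_alleles.append(founders[idx, np.arange(n_m)[None, :]])

        sample_ids.extend(
            np.repeat([f"{label}_{i}" for i in range(cfg.n_individuals)], 2)
        )
        pop_of_hap.extend([label] * n_h)

    return HaplotypeSet(
        markers=markers,
        sample_of_haplotype=np.asarray(sample_ids, dtype=object),
        alleles=np.vstack(all_alleles),
        populations=np.asarray(pop_of_hap, dtype=object),
        founders=founders_by_pop,
    )


def simulate_genotypes(
    freqs: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    markers: MarkerMap | None = None,
) -> GenotypeMatrix:
    """Genotypes drawn Binomial(2, p_il) per individual: no founder bottleneck.

    This is the haplotype-independence limit of the mosaic model and is the
    path to use when the target Fst itself must be recovered exactly in
    expectation.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if markers is None:
        markers = _draw_marker_map(cfg, rng)
    n_m = len(markers)
    blocks = []
    ids, pops = [], []
    for k, label in enumerate(cfg.pop_labels):
        blocks.append(
            rng.binomial(2, freqs[k], size=(cfg.n_individuals, n_m)).astype(np.int8)
        )
        ids.extend(f"{label}_{i}" for i in range(cfg.n_individuals))
        pops.extend([label] * cfg.n_individuals)
    dosage = np.vstack(blocks)
    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = MISSING
    return GenotypeMatrix(
        samples=SampleTable(
            ids=np.asarray(ids, dtype=object), populations=np.asarray(pops, dtype=object)
        ),
        markers=markers,
        dosage=dosage,
    )


def inject_sweep(
    h: HaplotypeSet, spec: SweepSpec, seed: int | np.random.Generator = 0
) -> HaplotypeSet:
    """Overwrite a core window around the focal marker with a donor haplotype.

    Each haplotype of ``spec.pop`` independently becomes a carrier with
    probability ``carrier_freq``; carriers take the donor's alleles at every
    marker within core_length_bp/2 of the focal position. The donor is founder
    0 of the swept population when founder metadata is present, otherwise the
    population's first haplotype. Other populations are untouched.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    if spec.pop not in set(h.populations):
        raise ValueError(f"population {spec.pop!r} not present")
    pos = h.markers.pos_bp
    focal_pos = pos[spec.focal_marker_index]
    half = spec.core_length_bp // 2
    core = np.flatnonzero((pos >= focal_pos - half) & (pos <= focal_pos + half))
    if len(core) == 0:
        raise ValueError("sweep core window contains no markers")

    if h.founders is not None and spec.pop in h.founders:
        donor = h.founders[spec.pop][0]
    else:
        donor = h.alleles[np.flatnonzero(h.populations == spec.pop)[0]]

    alleles = h.alleles.copy()
    target = np.flatnonzero(h.populations == spec.pop)
    carriers = target[rng.random(len(target)) < spec.carrier_freq]
    alleles[np.ix_(carriers, core)] = donor[core]
    return dataclasses.replace(h, alleles=alleles)


def haplotypes_to_genotypes(
    h: HaplotypeSet,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Collapse haplotype row pairs to dosages, then mask calls at random."""
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    g = h.to_genotypes()
    if missing_rate == 0.0:
        return g
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    dosage = g.dosage.copy()
    mask = rng.random(dosage.shape) < missing_rate
    dosage[mask] = MISSING
    return GenotypeMatrix(samples=g.samples, markers=g.markers, dosage=dosage)


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[HaplotypeSet, GenotypeMatrix, dict]:
    """Full generator chain: frequencies -> mosaic -> optional sweep -> genotypes.

    Returns the (possibly swept) haplotypes, the collapsed genotypes, and a
    truth dict holding the config and, when a sweep was injected, the core
    interval (chrom, start_bp, end_bp, focal position, swept population).
    """
    rng = np.random.default_rng(cfg.seed)
    freqs = sample_balding_nichols_freqs(cfg, rng)
    h = simulate_mosaic_haplotypes(freqs, cfg, rng)
    truth: dict = {"config": json.loads(cfg.to_json())}
    if cfg.sweep is not None:
        h = inject_sweep(h, cfg.sweep, rng)
        pos = h.markers.pos_bp
        focal_pos = int(pos[cfg.sweep.focal_marker_index])
        half = cfg.sweep.core_length_bp // 2
        truth["sweep"] = {
            "pop": cfg.sweep.pop,
            "chrom": cfg.chrom,
            "start_bp": max(1, focal_pos - half),
            "end_bp": focal_pos + half,
            "focal_pos_bp": focal_pos,
        }
    g = haplotypes_to_genotypes(h, cfg.missing_rate, rng)
    return h, g, truth
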