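import numpy as np
import pytest

from tropiscan.datamodel import (
    GenotypeMatrix,
    HaplotypeSet,
    MarkerMap,
    SampleTable,
)


def make_marker_map(positions, chrom="1", prefix="m"):
    positions = np.asarray(positions, dtype=np.int64)
    n = len(positions)
    return MarkerMap(
        chrom=np.asarray([chrom] * n, dtype=object),
        pos_bp=positions,
        ids=np.asarray([f"{prefix}{k}" for k in range(n)], dtype=object),
        allele_ref=np.asarray(["A"] * n, dtype=object),
        allele_alt=np.asarray(["G"] * n, dtype=object),
    )


def make_genotypes(dosage, populations=None, positions=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if populations is None:
        populations = ["pop"] * n
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    samples = SampleTable(
        ids=np.asarray([f"s{k}" for k in range(n)], dtype=object),
        populations=np.asarray(populations, dtype=object),
    )
    return GenotypeMatrix(
        samples=samples, markers=make_marker_map(positions), dosage=dosage
    )


def make_haplotypes(alleles, populations=None, positions=None):
    alleles = np.asarray(alleles, dtype=np.int8)
    n_h, m = alleles.shape
    assert n_h % 2 == 0
    if populations is None:
        populations = ["pop"] * n_h
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    sample_ids = np.repeat(
        np.asarray([f"s{k}" for k in range(n_h // 2)], dtype=object), 2
    )
    return HaplotypeSet(
        markers=make_marker_map(positions),
        sample_of_haplotype=sample_ids,
        alleles=alleles,
        populations=np.asarray(populations, dtype=object),
    )


@pytest.fixture(scope="session")
def two_pop_haplotypes():
    """Moderate two-population mosaic panel shared by structure/scan tests."""
    from tropiscan import simdata

    cfg = simdata.SimulationConfig(
        n_individuals=20, n_markers=600, chrom_length_bp=36_000_000, seed=7
    )
    h, g, _ = simdata.simulate_dataset(cfg)
    return h, g
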