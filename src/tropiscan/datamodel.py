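"""Shared containers: marker map, sample table, genotype and haplotype matrices.

Conventions used throughout the package:

* genome coordinates are 1-based inclusive internally; BED output converts to
  0-based half-open at write time;
* allele dosage counts copies of ``allele_alt`` and lives in {0, 1, 2} with a
  distinct sentinel :data:`MISSING` (= -1) for no-calls;
* phased haplotypes are binary (0 = ref, 1 = alt) with no missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call. Never conflated with dosage 0.
MISSING: int = -1


class FormatError(ValueError):
    """Malformed input file (column counts, separators, headers)."""


class DataError(ValueError):
    """Well-formed file with invalid content (e.g. >2 alleles at a locus)."""


@dataclass(frozen=True)
class MarkerMap:
    """Per-locus map: chromosome, 1-based physical position, id, alleles.

    Within a chromosome positions must be strictly increasing and ids unique.
    """

    chrom: np.ndarray
    pos_bp: np.ndarray
    ids: np.ndarray
    allele_ref: np.ndarray
    allele_alt: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in ("chrom", "pos_bp", "allele_ref", "allele_alt"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"MarkerMap field {name!r} length mismatch")
        if len(np.unique(self.ids)) != n:
            raise DataError("marker ids are not unique")
        pos = np.asarray(self.pos_bp)
        if np.any(pos <= 0):
            raise DataError("marker positions must be positive 1-based integers")
        for c in np.unique(self.chrom):
            p = pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise DataError(
                    f"positions on chromosome {c} are not strictly increasing"
                )

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, index: np.ndarray) -> "MarkerMap":
        index = np.asarray(index)
        return MarkerMap(
            chrom=self.chrom[index],
            pos_bp=self.pos_bp[index],
            ids=self.ids[index],
            allele_ref=self.allele_ref[index],
            allele_alt=self.allele_alt[index],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "id": self.ids,
                "allele_ref": self.allele_ref,
                "allele_alt": self.allele_alt,
            }
        )


@dataclass(frozen=True)
class SampleTable:
    """Individual ids (unique) and their single population label."""

    ids: np.ndarray
    populations: np.ndarray

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.populations):
            raise ValueError("SampleTable id/population length mismatch")
        if len(np.unique(self.ids)) != len(self.ids):
            raise DataError("sample ids are not unique")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, index: np.ndarray) -> "SampleTable":
        index = np.asarray(index)
        return SampleTable(ids=self.ids[index], populations=self.populations[index])

    def population_indices(self) -> Mapping[str, np.ndarray]:
        """Row indices per population label, in first-appearance order."""
        out: dict[str, np.ndarray] = {}
        for label in pd.unique(self.populations):
            out[str(label)] = np.flatnonzero(self.populations == label)
        return out


@dataclass(frozen=True)
class GenotypeMatrix:
    """Diploid allele-dosage matrix (individuals x loci).

    ``dosage[i, l]`` counts copies of ``markers.allele_alt[l]`` carried by
    individual ``i`` and is one of {0, 1, 2, MISSING}.
    """

    samples: SampleTable
    markers: MarkerMap
    dosage: np.ndarray

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.samples)}, {len(self.markers)})"
            )
        valid = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not valid.all():
            raise DataError("dosage entries must be in {0, 1, 2, MISSING}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=self.samples,
            markers=self.markers.subset(index),
            dosage=self.dosage[:, index],
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=self.samples.subset(index),
            markers=self.markers,
            dosage=self.dosage[index, :],
        )

    def restrict_populations(self, labels: Sequence[str]) -> "GenotypeMatrix":
        mask = np.isin(self.samples.populations, list(labels))
        return self.subset_samples(np.flatnonzero(mask))

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per locus from non-missing calls (NaN if none)."""
        d = np.ma.masked_equal(self.dosage, MISSING)
        n_called = d.count(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.asarray(d.sum(axis=0), dtype=float) / (2.0 * n_called)
        p = np.where(n_called > 0, p, np.nan)
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return (self.dosage == MISSING).mean(axis=0)


@dataclass(frozen=True)
class HaplotypeSet:
    """Phased binary haplotypes: 2 rows per individual, no missing values.

    Row ``2i`` is the left (first) allele of individual ``i`` and row ``2i+1``
    the right allele. ``populations`` carries one label per haplotype row.
    ``founders`` optionally retains the simulator's founder haplotypes per
    population (used as sweep donors); it is metadata, not part of equality.
    """

    markers: MarkerMap
    sample_of_haplotype: np.ndarray
    alleles: np.ndarray
    populations: np.ndarray
    founders: Mapping[str, np.ndarray] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        n_h, n_m = self.alleles.shape
        if n_h % 2 != 0:
            raise ValueError("haplotype count must be even (2 per individual)")
        if n_m != len(self.markers):
            raise ValueError("haplotype column count != marker count")
        if len(self.sample_of_haplotype) != n_h or len(self.populations) != n_h:
            raise ValueError("per-haplotype annotation length mismatch")
        ids = self.sample_of_haplotype
        if not np.array_equal(ids[0::2], ids[1::2]):
            raise DataError("rows 2i and 2i+1 must belong to the same individual")
        if not np.isin(self.alleles, (0, 1)).all():
            raise DataError("haplotype alleles must be binary with no missing")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0] // 2

    def subset_markers(self, index: np.ndarray) -> "HaplotypeSet":
        index = np.asarray(index)
        return replace(
            self, markers=self.markers.subset(index), alleles=self.alleles[:, index]
        )

    def restrict_population(self, label: str) -> "HaplotypeSet":
        mask = self.populations == label
        founders = None
        if self.founders is not None and label in self.founders:
            founders = {label: self.founders[label]}
        return HaplotypeSet(
            markers=self.markers,
            sample_of_haplotype=self.sample_of_haplotype[mask],
            alleles=self.alleles[mask, :],
            populations=self.populations[mask],
            founders=founders,
        )

    def to_genotypes(self) -> GenotypeMatrix:
        """Collapse row pairs by summation into a :class:`GenotypeMatrix`."""
        dosage = (self.alleles[0::2, :] + self.alleles[1::2, :]).astype(np.int8)
        samples = SampleTable(
            ids=self.sample_of_haplotype[0::2].copy(),
            populations=self.populations[0::2].copy(),
        )
        return GenotypeMatrix(samples=samples, markers=self.markers, dosage=dosage)
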