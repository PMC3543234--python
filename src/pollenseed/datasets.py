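"""Core data containers for diploid microsatellite genotypes and organelle haplotypes.

Conventions
-----------
* Genotypes are stored as an integer array of shape ``(n_individuals,
  n_loci, 2)``; allele labels are positive integers (repeat sizes or
  arbitrary codes) and ``0`` marks a missing gene copy.  A genotype is
  either fully typed or fully missing at a locus — half calls are
  rejected on construction rather than imputed, matching standard
  microsatellite scoring practice.
* Organelle haplotypes are small positive integer identifiers together
  with a symmetric haplotype-by-haplotype matrix of mutational
  differences (number of differing aligned sites).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = 0

__all__ = [
    "MISSING",
    "GenotypeDataset",
    "HaplotypeDataset",
    "AlleleFrequencyTable",
]


class DataFormatError(ValueError):
    """Raised when an input table violates the dataset invariants."""


@dataclass
class GenotypeDataset:
    """Diploid multilocus genotypes with population labels and coordinates.

    Parameters
    ----------
    individual_id
        Unique identifier per individual.
    population
        Population (e.g. estuary) label per individual.
    loci
        Ordered locus names.
    genotypes
        ``(n, n_loci, 2)`` integer array, ``0`` = missing gene copy.
    subpopulation
        Optional deme/transect label per individual.
    coords
        Optional ``(n, 2)`` array: ``(lat, lon)`` when ``coord_units ==
        "degrees"`` or planar ``(x, y)`` when ``coord_units == "meters"``.
    """

    individual_id: list[str]
    population: list[str]
    loci: list[str]
    genotypes: np.ndarray
    subpopulation: list[str] | None = None
    coords: np.ndarray | None = None
    coord_units: str | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        n = len(self.individual_id)
        if len(self.population) != n:
            raise DataFormatError("population labels do not match individuals")
        if self.genotypes.shape != (n, len(self.loci), 2):
            raise DataFormatError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{n} individuals x {len(self.loci)} loci x 2"
            )
        if len(set(self.individual_id)) != n:
            raise DataFormatError("duplicate individual_id")
        if (self.genotypes < 0).any():
            raise DataFormatError("allele labels must be positive (0 = missing)")
        half = (self.genotypes == MISSING).sum(axis=2) == 1
        if half.any():
            i, l = np.argwhere(half)[0]
            raise DataFormatError(
                f"half-missing genotype for {self.individual_id[i]} at locus "
                f"{self.loci[l]}; a genotype must carry 0 or 2 alleles"
            )
        if self.subpopulation is not None and len(self.subpopulation) != n:
            raise DataFormatError("subpopulation labels do not match individuals")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 2):
                raise DataFormatError("coords must be (n, 2)")
            if self.coord_units not in ("degrees", "meters"):
                raise DataFormatError("coord_units must be 'degrees' or 'meters'")

    # -- basic introspection ------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_id)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        """Unique population labels in order of first occurrence."""
        seen: dict[str, None] = {}
        for p in self.population:
            seen.setdefault(p)
        return list(seen)

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, n_loci)`` mask, True where the genotype is missing."""
        return (self.genotypes == MISSING).all(axis=2)

    def labels(self, by: str = "population") -> np.ndarray:
        """Group label per individual: ``population``, ``subpopulation`` or
        ``population:subpopulation``."""
        if by == "population":
            return np.asarray(self.population)
        if self.subpopulation is None:
            raise DataFormatError("dataset has no subpopulation column")
        if by == "subpopulation":
            return np.asarray(self.subpopulation)
        if by == "population:subpopulation":
            return np.asarray(
                [f"{p}:{s}" for p, s in zip(self.population, self.subpopulation)]
            )
        raise ValueError(f"unknown grouping {by!r}")

    def subset(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(
            individual_id=[self.individual_id[i] for i in index],
            population=[self.population[i] for i in index],
            loci=list(self.loci),
            genotypes=self.genotypes[index],
            subpopulation=(
                None
                if self.subpopulation is None
                else [self.subpopulation[i] for i in index]
            ),
            coords=None if self.coords is None else self.coords[index],
            coord_units=self.coord_units,
        )

    def allele_frequencies(self, by: str = "population") -> "AlleleFrequencyTable":
        """Relative allele frequencies per (group, locus) from non-missing copies."""
        groups = self.labels(by)
        table: dict[tuple[str, str], dict[int, float]] = {}
        copies: dict[tuple[str, str], int] = {}
        for g in dict.fromkeys(groups):
            rows = self.genotypes[groups == g]
            for l, locus in enumerate(self.loci):
                alleles = rows[:, l, :].ravel()
                alleles = alleles[alleles != MISSING]
                n = alleles.size
                copies[(g, locus)] = int(n)
                if n == 0:
                    table[(g, locus)] = {}
                    continue
                vals, counts = np.unique(alleles, return_counts=True)
                table[(g, locus)] = {
                    int(a): c / n for a, c in zip(vals, counts)
                }
        return AlleleFrequencyTable(frequencies=table, n_copies=copies)

    def equals(self, other: "GenotypeDataset") -> bool:
        if (
            self.individual_id != other.individual_id
            or self.population != other.population
            or self.loci != other.loci
            or not np.array_equal(self.genotypes, other.genotypes)
            or self.subpopulation != other.subpopulation
            or self.coord_units != other.coord_units
        ):
            return False
        if (self.coords is None) != (other.coords is None):
            return False
        if self.coords is not None and not np.allclose(
            self.coords, other.coords, atol=1e-9, equal_nan=True
        ):
            return False
        return True


@dataclass
class HaplotypeDataset:
    """Per-individual organelle haplotype assignments.

    ``distance_matrix[h-1, k-1]`` is the number of differing aligned sites
    between haplotypes ``h`` and ``k`` (1-based haplotype identifiers).
    """

    individual_id: list[str]
    population: list[str]
    haplotype_id: np.ndarray
    distance_matrix: np.ndarray

    def __post_init__(self) -> None:
        self.haplotype_id = np.asarray(self.haplotype_id, dtype=np.int64)
        self.distance_matrix = np.asarray(self.distance_matrix)
        n = len(self.individual_id)
        if len(self.population) != n or self.haplotype_id.shape != (n,):
            raise DataFormatError("haplotype table columns must align")
        if len(set(self.individual_id)) != n:
            raise DataFormatError("duplicate individual_id")
        if (self.haplotype_id < 1).any():
            raise DataFormatError("haplotype ids are positive integers")
        d = self.distance_matrix
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise DataFormatError("distance_matrix must be square")
        if not np.array_equal(d, d.T) or (np.diag(d) != 0).any() or (d < 0).any():
            raise DataFormatError(
                "distance_matrix must be symmetric, non-negative, zero diagonal"
            )
        if self.haplotype_id.max(initial=0) > d.shape[0]:
            raise DataFormatError("haplotype id missing from distance_matrix")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_id)

    @property
    def n_haplotypes(self) -> int:
        """Number of distinct haplotypes observed in the sample."""
        return int(np.unique(self.haplotype_id).size)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population:
            seen.setdefault(p)
        return list(seen)

    def pairwise_individual_distances(self) -> np.ndarray:
        """``(n, n)`` mutational differences between individuals' haplotypes."""
        idx = self.haplotype_id - 1
        return self.distance_matrix[np.ix_(idx, idx)].astype(float)

    def haplotype_counts(self, population: str | None = None) -> dict[int, int]:
        hap = self.haplotype_id
        if population is not None:
            hap = hap[np.asarray(self.population) == population]
        vals, counts = np.unique(hap, return_counts=True)
        return {int(h): int(c) for h, c in zip(vals, counts)}

    def subset(self, index: np.ndarray) -> "HaplotypeDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return HaplotypeDataset(
            individual_id=[self.individual_id[i] for i in index],
            population=[self.population[i] for i in index],
            haplotype_id=self.haplotype_id[index],
            distance_matrix=self.distance_matrix,
        )


@dataclass
class AlleleFrequencyTable:
    """Relative allele frequencies per (group, locus).

    ``frequencies[(group, locus)]`` maps allele label to relative
    frequency among the ``n_copies[(group, locus)]`` non-missing gene
    copies; the frequencies sum to 1 whenever ``n_copies > 0``.
    """

    frequencies: dict[tuple[str, str], dict[int, float]]
    n_copies: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, freqs in self.frequencies.items():
            n = self.n_copies.get(key, 0)
            if n > 0:
                total = sum(freqs.values())
                if abs(total - 1.0) > 1e-9:
                    raise DataFormatError(
                        f"frequencies for {key} sum to {total}, not 1"
                    )

    def __getitem__(self, key: tuple[str, str]) -> dict[int, float]:
        return self.frequencies[key]
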