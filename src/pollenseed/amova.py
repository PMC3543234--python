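"""One-level analysis of molecular variance (among vs. within populations).

The machinery is the classic squared-distance ANOVA of Excoffier,
Smouse & Quattro: sums of squared inter-unit distances partitioned into
among- and within-population sums of squares, variance components via
the unequal-sample-size coefficient, Phi_ST as the among-population
fraction, and significance by permuting individuals among populations.

Two front ends share it:

* nuclear genotypes — units are gene copies (two per diploid
  individual) and the squared distance between two copies is the number
  of loci at which they carry different alleles (the "F_ST-based"
  allele-identity choice, not a repeat-size R_ST);
* organelle haplotypes — units are individuals and the squared distance
  is the squared number of differing aligned sites between their
  haplotypes.

Permutations move whole individuals (a diploid's two gene copies travel
together).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import MISSING, GenotypeDataset, HaplotypeDataset

__all__ = ["Amova", "AmovaResults", "amova_nuclear", "amova_haplotype"]


class UndefinedStatisticError(ValueError):
    """Total molecular variance is zero: Phi_ST is undefined."""


@dataclass
class AmovaResults:
    """Variance components, Phi_ST and permutation significance."""

    sigma2_among: float
    sigma2_within: float
    phi_st: float
    p_value: float | None
    n_perm: int
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float

    @property
    def percent_among(self) -> float:
        """Percent of total variance among populations (floored at 0 when the
        among-component estimate is negative; raw value stays in sigma2_among)."""
        total = max(self.sigma2_among, 0.0) + self.sigma2_within
        return 100.0 * max(self.sigma2_among, 0.0) / total

    @property
    def percent_within(self) -> float:
        return 100.0 - self.percent_among

    def summary(self) -> str:
        p = "-" if self.p_value is None else f"{self.p_value:.4g}"
        return "\n".join(
            [
                "AMOVA (one level: among / within populations)",
                "=" * 55,
                f"{'source':<18}{'df':>5}{'SS':>10}{'sigma2':>10}{'% total':>9}",
                f"{'among pops':<18}{self.df_among:>5}{self.ss_among:>10.3f}"
                f"{self.sigma2_among:>10.4f}{self.percent_among:>9.2f}",
                f"{'within pops':<18}{self.df_within:>5}{self.ss_within:>10.3f}"
                f"{self.sigma2_within:>10.4f}{self.percent_within:>9.2f}",
                "-" * 55,
                f"Phi_ST = {self.phi_st:.4f}   permutation p = {p} "
                f"({self.n_perm} permutations)",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "sigma2_among": self.sigma2_among,
            "sigma2_within": self.sigma2_within,
            "percent_among": self.percent_among,
            "percent_within": self.percent_within,
            "Phi_ST": self.phi_st,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
        }


def _one_level_anova(sqd: np.ndarray, groups: np.ndarray):
    """Variance components from a squared-distance matrix over units.

    Returns (sigma_a, sigma_w, ss_among, ss_within, df_a, df_w).
    """
    n = len(groups)
    labels, inverse = np.unique(groups, return_inverse=True)
    g = len(labels)
    ss_total = sqd.sum() / (2.0 * n)
    ss_within = 0.0
    sizes = np.empty(g)
    for k in range(g):
        idx = np.flatnonzero(inverse == k)
        sizes[k] = len(idx)
        ss_within += sqd[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_among = ss_total - ss_within
    df_a, df_w = g - 1, n - g
    ms_within = ss_within / df_w
    n_c = (n - (sizes**2).sum() / n) / df_a
    sigma_a = (ss_among / df_a - ms_within) / n_c
    return sigma_a, ms_within, ss_among, ss_within, df_a, df_w


def _fit(
    sqd: np.ndarray,
    ind_groups: np.ndarray,
    unit_of_individual: np.ndarray,
    n_perm: int,
    seed,
) -> AmovaResults:
    """Run the ANOVA with units expanded from individuals.

    ``unit_of_individual`` maps each unit (row of ``sqd``) to the
    individual it belongs to, so permuting individuals permutes units in
    blocks.
    """
    unit_groups = ind_groups[unit_of_individual]
    sigma_a, sigma_w, ss_a, ss_w, df_a, df_w = _one_level_anova(sqd, unit_groups)
    if sigma_a + sigma_w <= 0:
        raise UndefinedStatisticError(
            "no molecular variance in the sample; Phi_ST undefined"
        )
    phi = sigma_a / (sigma_a + sigma_w)

    p = None
    if n_perm:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(ind_groups)
            s_a, s_w, *_ = _one_level_anova(sqd, perm[unit_of_individual])
            if s_a + s_w > 0 and s_a / (s_a + s_w) >= phi:
                exceed += 1
        p = (1 + exceed) / (n_perm + 1)

    return AmovaResults(
        sigma2_among=float(sigma_a),
        sigma2_within=float(sigma_w),
        phi_st=float(phi),
        p_value=p,
        n_perm=n_perm,
        df_among=df_a,
        df_within=df_w,
        ss_among=float(ss_a),
        ss_within=float(ss_w),
    )


class Amova:
    """One-level AMOVA model; build from genotypes or haplotypes, then fit.

    >>> res = Amova.from_genotypes(ds).fit(n_perm=10_000, seed=1)
    """

    def __init__(self, sqd: np.ndarray, ind_groups: np.ndarray, unit_of_individual):
        self._sqd = sqd
        self._groups = np.asarray(ind_groups)
        self._units = np.asarray(unit_of_individual)
        labels, counts = np.unique(self._groups, return_counts=True)
        if len(labels) < 2:
            raise ValueError("need at least two populations")
        if (counts < 2).any():
            raise ValueError(
                f"populations with <2 individuals: {labels[counts < 2].tolist()}"
            )

    @classmethod
    def from_genotypes(
        cls, dataset: GenotypeDataset, by: str = "population"
    ) -> "Amova":
        geno = dataset.genotypes
        n, L, _ = geno.shape
        # gene copies in stored order; allele-identity distances are
        # invariant to the (unknown) phase
        copies = geno.transpose(0, 2, 1).reshape(2 * n, L)
        present = copies != MISSING
        sqd = np.zeros((2 * n, 2 * n))
        for l in range(L):
            col = copies[:, l]
            ok = present[:, l]
            diff = (col[:, None] != col[None, :]) & ok[:, None] & ok[None, :]
            sqd += diff
        unit_of_individual = np.repeat(np.arange(n), 2)
        return cls(sqd, dataset.labels(by), unit_of_individual)

    @classmethod
    def from_haplotypes(
        cls, dataset: HaplotypeDataset, by: str = "population"
    ) -> "Amova":
        if dataset.n_haplotypes < 2:
            raise UndefinedStatisticError(
                "all individuals share one haplotype; Phi_ST undefined"
            )
        d = dataset.pairwise_individual_distances()
        groups = np.asarray(dataset.population)
        return cls(d**2, groups, np.arange(dataset.n_individuals))

    def fit(self, n_perm: int = 10_000, seed: int | None = None) -> AmovaResults:
        return _fit(self._sqd, self._groups, self._units, n_perm, seed)


def amova_nuclear(
    dataset: GenotypeDataset,
    by: str = "population",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> AmovaResults:
    return Amova.from_genotypes(dataset, by).fit(n_perm=n_perm, seed=seed)


def amova_haplotype(
    dataset: HaplotypeDataset,
    by: str = "population",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> AmovaResults:
    return Amova.from_haplotypes(dataset, by).fit(n_perm=n_perm, seed=seed)
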