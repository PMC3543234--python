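"""Pollen-vs-seed gene-flow inference from contrasting nuclear and
organelle structure.

Two classical results drive this module, both exploiting the fact that
a maternally inherited organelle moves only with seed while biparental
nuclear genes move with both pollen and seed:

* **Ennos ratio** — the pollen-to-seed migration ratio
  ``r = [(1/F_b - 1)(1 + F_IS) - 2(1/G_m - 1)] / (1/G_m - 1)``
  from the biparental F_ST (``F_b``), the inbreeding coefficient
  ``F_IS`` and the maternal G_ST (``G_m``).
* **Hamilton-Miller test** — under the null of equal pollen and seed
  migration the maternal F_ST expected from the biparental F_ST is
  ``a_b F_b / (a_m + (a_b - a_m) F_b)`` with ``a_m = 2`` (a haploid,
  uniparental genome) and ``a_b = 4 + 2t`` (a diploid biparental genome
  whose effective size rises with the outcrossing rate ``t``); the null
  is rejected when the +/- 2 SE confidence intervals of expected and
  observed maternal differentiation fail to overlap.

A handy algebraic consequence: when the observed G_m equals its
expectation, the Ennos ratio evaluates to ``1 + F_IS`` (not exactly 1),
an internal tension between the two methods that users should keep in
mind when reading ``r`` near the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import HaplotypeDataset
from .fstats import WeirCockerhamFst, jackknife_se, outcrossing_rate

__all__ = [
    "haplotype_diversity",
    "nei_gst_haplotypes",
    "expected_maternal_fst",
    "ennos_ratio",
    "hamilton_miller_test",
    "PollenSeedGeneFlow",
    "GeneFlowResults",
]

A_MAT = 2.0


class UndefinedStatisticError(ValueError):
    pass


def haplotype_diversity(dataset: HaplotypeDataset) -> pd.DataFrame:
    """Nei's unbiased haplotype diversity per population.

    H_d = n/(n-1) (1 - sum p_i^2); requires n >= 2 individuals.
    """
    rows = []
    for pop in dataset.populations:
        counts = np.array(list(dataset.haplotype_counts(pop).values()), dtype=float)
        n = counts.sum()
        if n < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 individuals")
        p = counts / n
        h_d = n / (n - 1) * (1.0 - (p**2).sum())
        rows.append((pop, int(n), len(counts), float(h_d)))
    return pd.DataFrame(rows, columns=["population", "n", "k", "H_d"]).set_index(
        "population"
    )


def _gst_from_counts(counts: np.ndarray) -> float:
    """G_ST from a population x haplotype count matrix (unbiased H_S, H_T)."""
    n_k = counts.sum(axis=1)
    keep = n_k >= 2
    counts = counts[keep]
    n_k = n_k[keep]
    if len(n_k) < 2:
        return np.nan
    p_k = counts / n_k[:, None]
    h_k = n_k / (n_k - 1) * (1.0 - (p_k**2).sum(axis=1))
    h_s = float((n_k * h_k).sum() / n_k.sum())
    pooled = counts.sum(axis=0)
    n_tot = pooled.sum()
    p_bar = pooled / n_tot
    h_t = float(n_tot / (n_tot - 1) * (1.0 - (p_bar**2).sum()))
    if h_t <= 0:
        return np.nan
    return (h_t - h_s) / h_t


def nei_gst_haplotypes(dataset: HaplotypeDataset) -> tuple[float, float]:
    """Nei's G_ST over organelle haplotype frequencies, with a
    delete-one-population jackknife SE.

    Returns ``(G_ST, SE)``.  Raises when the pooled sample is
    monomorphic (H_T = 0).
    """
    pops = dataset.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    haps = sorted(dataset.haplotype_counts().keys())
    counts = np.zeros((len(pops), len(haps)))
    for i, pop in enumerate(pops):
        for h, c in dataset.haplotype_counts(pop).items():
            counts[i, haps.index(h)] = c
    gst = _gst_from_counts(counts)
    if np.isnan(gst):
        raise UndefinedStatisticError("pooled sample monomorphic: G_ST undefined")
    loo = []
    for k in range(len(pops)):
        g = _gst_from_counts(np.delete(counts, k, axis=0))
        if not np.isnan(g):
            loo.append(g)
    se = jackknife_se(np.asarray(loo)) if len(loo) >= 2 else np.nan
    return float(gst), float(se)


def expected_maternal_fst(fst_bipar: float, t: float) -> float:
    """Expected maternal-marker F_ST under equal pollen and seed migration.

    ``a_b F_b / (a_m + (a_b - a_m) F_b)`` with a_m = 2 and a_b = 4 + 2t.
    Fixed points at F_b = 0 and F_b = 1 for any outcrossing rate.
    """
    if not (0.0 <= fst_bipar <= 1.0):
        raise ValueError("F_ST must lie in [0, 1]")
    if not (0.0 <= t <= 1.0):
        raise ValueError("t must lie in [0, 1]")
    a_b = 4.0 + 2.0 * t
    return a_b * fst_bipar / (A_MAT + (a_b - A_MAT) * fst_bipar)


def ennos_ratio(fst_bipar: float, fis: float, gst_mat: float) -> float:
    """Pollen-to-seed migration ratio r (Ennos).

    ``r = [(1/F_b - 1)(1 + F_IS) - 2(1/G_m - 1)] / (1/G_m - 1)``.
    Negative values are passed through: they indicate pollen flow at or
    below the level implied by seed flow alone.
    """
    if not (0.0 < fst_bipar < 1.0):
        raise ValueError("F_ST must lie strictly in (0, 1)")
    if not (0.0 < gst_mat < 1.0):
        raise ValueError("G_ST must lie strictly in (0, 1)")
    seed_term = 1.0 / gst_mat - 1.0
    return ((1.0 / fst_bipar - 1.0) * (1.0 + fis) - 2.0 * seed_term) / seed_term


def hamilton_miller_test(
    expected: float,
    se_expected: float,
    observed: float,
    se_observed: float,
) -> dict:
    """Compare expected vs observed maternal differentiation by +/- 2 SE
    interval overlap (closed intervals: touching endpoints overlap).

    ``se_expected`` is the SE of the *biparental* F_ST: the interval
    around the transformed expectation keeps the nuclear half-width.
    """
    if se_expected < 0 or se_observed < 0:
        raise ValueError("standard errors must be non-negative")
    exp_ci = (expected - 2 * se_expected, expected + 2 * se_expected)
    obs_ci = (observed - 2 * se_observed, observed + 2 * se_observed)
    rejected = exp_ci[1] < obs_ci[0] or obs_ci[1] < exp_ci[0]
    return {
        "expected_ci": exp_ci,
        "observed_ci": obs_ci,
        "H0_rejected": bool(rejected),
    }


@dataclass
class GeneFlowResults:
    """Pollen/seed gene-flow comparison for one species or dataset."""

    fst_bipar: float
    se_fst_bipar: float
    fis: float
    t: float
    gst_mat: float
    se_gst_mat: float
    fst_mat_expected: float
    expected_ci: tuple[float, float]
    observed_ci: tuple[float, float]
    r: float
    a_mat: float
    a_bipar: float
    h0_rejected: bool

    def summary(self) -> str:
        verdict = "REJECTED" if self.h0_rejected else "not rejected"
        return "\n".join(
            [
                "Pollen vs seed gene flow",
                "=" * 58,
                f"nuclear  F_ST = {self.fst_bipar:.4f} (SE {self.se_fst_bipar:.4f})"
                f"   F_IS = {self.fis:.4f}   t = {self.t:.4f}",
                f"organelle G_ST = {self.gst_mat:.4f} (SE {self.se_gst_mat:.4f})"
                f"   95% CI {self.observed_ci[0]:.4f}-{self.observed_ci[1]:.4f}",
                f"expected maternal F_ST = {self.fst_mat_expected:.4f}"
                f"   95% CI {self.expected_ci[0]:.4f}-{self.expected_ci[1]:.4f}"
                f"   (a_mat = {self.a_mat:.1f}, a_bipar = {self.a_bipar:.4f})",
                f"Ennos r (pollen/seed) = {self.r:.2f}",
                f"H0 m_pollen = m_seed: {verdict} (+/- 2 SE interval overlap)",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "F_ST_bipar": self.fst_bipar,
            "SE_FST_bipar": self.se_fst_bipar,
            "F_IS": self.fis,
            "t": self.t,
            "G_ST_mat": self.gst_mat,
            "SE_GST_mat": self.se_gst_mat,
            "F_ST_mat_expected": self.fst_mat_expected,
            "expected_CI": list(self.expected_ci),
            "observed_CI": list(self.observed_ci),
            "r": self.r,
            "a_mat": self.a_mat,
            "a_bipar": self.a_bipar,
            "H0_rejected": self.h0_rejected,
        }


class PollenSeedGeneFlow:
    """Model for the pollen/seed migration comparison.

    Build either from raw datasets (nuclear genotypes + organelle
    haplotypes) or directly from published summary statistics (the
    "replay" situation where only the table values survive).
    """

    def __init__(
        self,
        fst_bipar: float,
        se_fst_bipar: float,
        fis: float,
        gst_mat: float,
        se_gst_mat: float,
    ):
        self.fst_bipar = fst_bipar
        self.se_fst_bipar = se_fst_bipar
        self.fis = fis
        self.gst_mat = gst_mat
        self.se_gst_mat = se_gst_mat

    @classmethod
    def from_statistics(cls, fst_bipar, se_fst_bipar, fis, gst_mat, se_gst_mat):
        return cls(fst_bipar, se_fst_bipar, fis, gst_mat, se_gst_mat)

    @classmethod
    def from_datasets(cls, genotypes, haplotypes: HaplotypeDataset, by="population"):
        nuc = WeirCockerhamFst(genotypes, by).fit()
        gst, se_gst = nei_gst_haplotypes(haplotypes)
        return cls(nuc.fst, nuc.se_fst, nuc.fis, gst, se_gst)

    def fit(self) -> GeneFlowResults:
        # a sampling-noise negative F_IS maps to t > 1; cap at complete
        # outcrossing before entering the Hamilton-Miller expectation
        t = min(1.0, max(0.0, outcrossing_rate(self.fis)))
        expected = expected_maternal_fst(self.fst_bipar, t)
        test = hamilton_miller_test(
            expected, self.se_fst_bipar, self.gst_mat, self.se_gst_mat
        )
        r = ennos_ratio(self.fst_bipar, self.fis, self.gst_mat)
        return GeneFlowResults(
            fst_bipar=self.fst_bipar,
            se_fst_bipar=self.se_fst_bipar,
            fis=self.fis,
            t=t,
            gst_mat=self.gst_mat,
            se_gst_mat=self.se_gst_mat,
            fst_mat_expected=expected,
            expected_ci=test["expected_ci"],
            observed_ci=test["observed_ci"],
            r=r,
            a_mat=A_MAT,
            a_bipar=4.0 + 2.0 * t,
            h0_rejected=test["H0_rejected"],
        )
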