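"""Nuclear-marker statistics: heterozygosities, Weir-Cockerham F-statistics,
pairwise F_ST with permutation tests, outcrossing rate, null-allele frequency.

The F_ST / F_IS estimators are Weir & Cockerham's (1984) theta and f,
built from the among-population (a), among-individual-within-population
(b) and within-individual (c) variance components.  Multilocus estimates
are ratios of components summed over alleles and loci — never means of
per-locus ratios — and standard errors come from a delete-one-locus
jackknife, the convention of ARLEQUIN and SPAGeDi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import MISSING, GenotypeDataset

__all__ = [
    "summary_diversity",
    "wc_variance_components",
    "WeirCockerhamFst",
    "FStatsResults",
    "wc_f_statistics",
    "PairwiseFst",
    "PairwiseFstResults",
    "pairwise_fst",
    "outcrossing_rate",
    "brookfield_null_frequency",
    "null_allele_table",
    "jackknife_se",
]


class MonomorphicDataError(ValueError):
    """All loci are monomorphic: F-statistics are undefined."""


def summary_diversity(dataset: GenotypeDataset, by: str = "population") -> pd.DataFrame:
    """Per (group, locus) sample size, allele count, H_o and H_e.

    H_o is the fraction of heterozygous individuals among those typed;
    H_e is Nei's gene diversity ``1 - sum(p^2)`` without small-sample
    correction (the descriptive-statistics convention).
    """
    groups = dataset.labels(by)
    rows = []
    for g in dict.fromkeys(groups):
        geno = dataset.genotypes[groups == g]
        for l, locus in enumerate(dataset.loci):
            pair = geno[:, l, :]
            typed = pair[(pair != MISSING).all(axis=1)]
            n = len(typed)
            if n == 0:
                rows.append((g, locus, 0, np.nan, np.nan, np.nan))
                continue
            alleles, counts = np.unique(typed.ravel(), return_counts=True)
            p = counts / counts.sum()
            h_o = float((typed[:, 0] != typed[:, 1]).mean())
            h_e = float(1.0 - (p**2).sum())
            rows.append((g, locus, n, len(alleles), h_o, h_e))
    return pd.DataFrame(
        rows, columns=["group", "locus", "n", "n_alleles", "H_o", "H_e"]
    ).set_index(["group", "locus"])


# ---------------------------------------------------------------------------
# Weir & Cockerham variance components


def wc_variance_components(
    genotypes: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    """Per-locus Weir-Cockerham components summed over alleles.

    Parameters
    ----------
    genotypes
        ``(n, L, 2)`` allele array, 0 = missing.
    groups
        group label per individual.

    Returns
    -------
    ``(L, 3)`` array of (a, b, c) per locus; NaN rows where the locus is
    not estimable (fewer than two populations typed, or n_bar <= 1).
    """
    genotypes = np.asarray(genotypes)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups))
    L = genotypes.shape[1]
    out = np.full((L, 3), np.nan)

    for l in range(L):
        pair = genotypes[:, l, :]
        typed = (pair != MISSING).all(axis=1)
        n_i, p_i, h_i, alleles = [], [], [], set()
        for g in labels:
            rows = pair[typed & (groups == g)]
            if len(rows) == 0:
                continue
            n_i.append(len(rows))
            vals, counts = np.unique(rows.ravel(), return_counts=True)
            freqs = dict(zip(vals.tolist(), (counts / counts.sum()).tolist()))
            alleles.update(freqs)
            p_i.append(freqs)
            het = rows[:, 0] != rows[:, 1]
            h_i.append(
                {
                    int(a): float(
                        (het & ((rows[:, 0] == a) | (rows[:, 1] == a))).mean()
                    )
                    for a in vals
                }
            )
        r = len(n_i)
        if r < 2:
            continue
        n_arr = np.asarray(n_i, dtype=float)
        n_bar = n_arr.mean()
        if n_bar <= 1:
            continue
        n_c = (r * n_bar - (n_arr**2).sum() / (r * n_bar)) / (r - 1)
        if n_c <= 0:
            continue
        a_sum = b_sum = c_sum = 0.0
        for al in sorted(alleles):
            p = np.array([d.get(al, 0.0) for d in p_i])
            h = np.array([d.get(al, 0.0) for d in h_i])
            p_bar = (n_arr * p).sum() / (r * n_bar)
            s2 = (n_arr * (p - p_bar) ** 2).sum() / ((r - 1) * n_bar)
            h_bar = (n_arr * h).sum() / (r * n_bar)
            a = (n_bar / n_c) * (
                s2
                - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
            )
            b = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar)
                - (r - 1) / r * s2
                - (2 * n_bar - 1) / (4 * n_bar) * h_bar
            )
            c = h_bar / 2
            a_sum += a
            b_sum += b
            c_sum += c
        out[l] = (a_sum, b_sum, c_sum)
    return out


def jackknife_se(values: np.ndarray) -> float:
    """Delete-one jackknife SE from the leave-one-out estimates."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    k = len(values)
    if k < 2:
        return np.nan
    return float(np.sqrt((k - 1) / k * ((values - values.mean()) ** 2).sum()))


def _ratio(num: float, den: float) -> float:
    return num / den if den != 0 else np.nan


@dataclass
class FStatsResults:
    """Multilocus Weir-Cockerham estimates with jackknife errors."""

    fst: float
    fis: float
    fit: float
    se_fst: float
    se_fis: float
    t: float
    se_t: float
    per_locus: pd.DataFrame
    components: np.ndarray = field(repr=False)
    loci: list[str] = field(default_factory=list)
    grouping: str = "population"

    def summary(self) -> str:
        lines = [
            "Weir-Cockerham F-statistics",
            "=" * 43,
            f"grouping: {self.grouping}   loci: {len(self.loci)}",
            f"F_ST  {self.fst: .4f}  (SE {self.se_fst:.4f})",
            f"F_IS  {self.fis: .4f}  (SE {self.se_fis:.4f})",
            f"F_IT  {self.fit: .4f}",
            f"t     {self.t: .4f}  (SE {self.se_t:.4f})   [t = (1-F_IS)/(1+F_IS)]",
            "-" * 43,
            self.per_locus.round(4).to_string(),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "F_ST": self.fst,
            "F_IS": self.fis,
            "F_IT": self.fit,
            "SE_FST": self.se_fst,
            "SE_FIS": self.se_fis,
            "t": self.t,
            "SE_t": self.se_t,
            "per_locus": self.per_locus.to_dict(orient="index"),
        }


class WeirCockerhamFst:
    """Model object for multilocus Weir-Cockerham F-statistics.

    Parameters
    ----------
    dataset
        Diploid genotypes with group labels.
    by
        Grouping column: ``population`` (default), ``subpopulation`` or
        ``population:subpopulation``.
    """

    def __init__(self, dataset: GenotypeDataset, by: str = "population"):
        self.dataset = dataset
        self.by = by
        groups = dataset.labels(by)
        if len(dict.fromkeys(groups)) < 2:
            raise ValueError("need at least two populations")
        self.groups = groups

    def fit(self) -> FStatsResults:
        comp = wc_variance_components(self.dataset.genotypes, self.groups)
        if np.all(np.isnan(comp)) or np.nansum(comp) == 0:
            raise MonomorphicDataError("all loci monomorphic or not estimable")
        a, b, c = np.nansum(comp, axis=0)
        fst = _ratio(a, a + b + c)
        fis = _ratio(b, b + c)
        fit = _ratio(a + b, a + b + c)

        ok = ~np.isnan(comp).any(axis=1)
        per_locus = pd.DataFrame(
            {
                "F_ST": [
                    _ratio(comp[l, 0], comp[l].sum()) if ok[l] else np.nan
                    for l in range(len(self.dataset.loci))
                ],
                "F_IS": [
                    _ratio(comp[l, 1], comp[l, 1] + comp[l, 2]) if ok[l] else np.nan
                    for l in range(len(self.dataset.loci))
                ],
            },
            index=pd.Index(self.dataset.loci, name="locus"),
        )

        ok_idx = np.flatnonzero(ok)
        loo_fst, loo_fis = [], []
        for l in ok_idx:
            a_, b_, c_ = comp[ok_idx[ok_idx != l]].sum(axis=0)
            loo_fst.append(_ratio(a_, a_ + b_ + c_))
            loo_fis.append(_ratio(b_, b_ + c_))
        se_fst = jackknife_se(np.asarray(loo_fst))
        se_fis = jackknife_se(np.asarray(loo_fis))
        t = outcrossing_rate(fis) if fis > -1 else np.nan
        se_t = jackknife_se(
            np.asarray([outcrossing_rate(f) for f in loo_fis if f > -1])
        )
        return FStatsResults(
            fst=fst,
            fis=fis,
            fit=fit,
            se_fst=se_fst,
            se_fis=se_fis,
            t=t,
            se_t=se_t,
            per_locus=per_locus,
            components=comp,
            loci=list(self.dataset.loci),
            grouping=self.by,
        )


def wc_f_statistics(dataset: GenotypeDataset, by: str = "population") -> FStatsResults:
    """Functional wrapper: ``WeirCockerhamFst(dataset, by).fit()``."""
    return WeirCockerhamFst(dataset, by).fit()


# ---------------------------------------------------------------------------
# pairwise F_ST


def _theta(genotypes: np.ndarray, groups: np.ndarray) -> float:
    comp = wc_variance_components(genotypes, groups)
    a, b, c = np.nansum(comp, axis=0)
    return _ratio(a, a + b + c)


@dataclass
class PairwiseFstResults:
    fst: pd.DataFrame
    p_value: pd.DataFrame
    n_perm: int

    def summary(self) -> str:
        return (
            "Pairwise Weir-Cockerham F_ST (lower: theta, upper: permutation p, "
            f"{self.n_perm} permutations)\n"
            + self.fst.round(4)
            .where(np.tril(np.ones(self.fst.shape, bool), -1))
            .combine_first(
                self.p_value.round(4).where(
                    np.triu(np.ones(self.fst.shape, bool), 1)
                )
            )
            .to_string(na_rep="-")
        )


class PairwiseFst:
    """Pairwise Weir-Cockerham theta between all population pairs, with a
    permutation test shuffling individuals between the two populations."""

    def __init__(self, dataset: GenotypeDataset, by: str = "population"):
        self.dataset = dataset
        self.groups = dataset.labels(by)
        self.pops = list(dict.fromkeys(self.groups))
        counts = {p: int((self.groups == p).sum()) for p in self.pops}
        small = [p for p, c in counts.items() if c < 2]
        if small:
            raise ValueError(f"populations with <2 individuals: {small}")

    def fit(self, n_perm: int = 10_000, seed: int | None = None) -> PairwiseFstResults:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        k = len(self.pops)
        fst = np.full((k, k), np.nan)
        pval = np.full((k, k), np.nan)
        for i in range(k):
            for j in range(i + 1, k):
                idx = np.flatnonzero(
                    (self.groups == self.pops[i]) | (self.groups == self.pops[j])
                )
                geno = self.dataset.genotypes[idx]
                labels = self.groups[idx]
                obs = _theta(geno, labels)
                exceed = 0
                for _ in range(n_perm):
                    perm = rng.permutation(labels)
                    if _theta(geno, perm) >= obs:
                        exceed += 1
                fst[i, j] = fst[j, i] = obs
                pval[i, j] = pval[j, i] = (1 + exceed) / (n_perm + 1)
        return PairwiseFstResults(
            fst=pd.DataFrame(fst, index=self.pops, columns=self.pops),
            p_value=pd.DataFrame(pval, index=self.pops, columns=self.pops),
            n_perm=n_perm,
        )


def pairwise_fst(
    dataset: GenotypeDataset,
    n_perm: int = 10_000,
    seed: int | None = None,
    by: str = "population",
) -> PairwiseFstResults:
    return PairwiseFst(dataset, by).fit(n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# derived scalar statistics


def outcrossing_rate(fis: float) -> float:
    """Equilibrium outcrossing rate t = (1 - F_IS)/(1 + F_IS).

    Inverts the inbreeding-equilibrium relation F = (1-t)/(1+t) of a
    mixed-mating population.  For F_IS in [0, 1] the result is clamped
    to [0, 1] to absorb rounding at the boundaries.
    """
    if fis <= -1:
        raise ValueError("F_IS must exceed -1")
    t = (1.0 - fis) / (1.0 + fis)
    if 0.0 <= fis <= 1.0:
        t = min(max(t, 0.0), 1.0)
    return t


def brookfield_null_frequency(h_e: float, h_o: float) -> float:
    """Brookfield (1996) method-1 null-allele frequency estimate.

    q_null = (H_e - H_o) / (1 + H_e).  An excess of heterozygotes gives
    a (slightly) negative estimate, which is passed through unchanged.
    """
    if not (0.0 <= h_e <= 1.0 and 0.0 <= h_o <= 1.0):
        raise ValueError("heterozygosities must lie in [0, 1]")
    return (h_e - h_o) / (1.0 + h_e)


def null_allele_table(dataset: GenotypeDataset, by: str = "population") -> pd.DataFrame:
    """Brookfield method-1 null-allele frequency per (group, locus)."""
    div = summary_diversity(dataset, by)
    q = [
        brookfield_null_frequency(row.H_e, row.H_o)
        if not (np.isnan(row.H_e) or np.isnan(row.H_o))
        else np.nan
        for row in div.itertuples()
    ]
    return div.assign(q_null=q)[["q_null"]]
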