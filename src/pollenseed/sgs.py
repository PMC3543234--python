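"""Spatial genetic structure within populations.

Pairwise Loiselle kinship coefficients (nuclear) or a distance-based
kinship analogue (organelle), binned into distance classes with
near-constant pair counts, regressed on ln(distance) to give the slope
b_ld, with a delete-one-locus jackknife SE and a permutation test that
shuffles spatial locations among individuals.  The strength of SGS is
summarised by Sp = -b_ld / (1 - F_A), where F_A is the mean kinship in
the first distance class (nearest neighbours).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import MISSING, GenotypeDataset, HaplotypeDataset

__all__ = [
    "KinshipMatrix",
    "loiselle_kinship",
    "organelle_kinship_analogue",
    "make_distance_classes",
    "KinshipDistanceRegression",
    "SgsResults",
    "kinship_distance_regression",
    "sp_statistic",
]

DEFAULT_MAX_DISTANCE = 10_000.0


class MonomorphicReferenceError(ValueError):
    """Kinship undefined: the reference sample is monomorphic."""


@dataclass
class KinshipMatrix:
    """Pairwise kinship with per-locus pieces retained for jackknifing.

    ``values[i, j]`` is the multilocus kinship (ratio of summed per-locus
    numerators over summed denominators); NaN marks pairs with no
    co-typed locus.  ``per_locus_num``/``per_locus_den`` let callers
    rebuild leave-one-locus-out kinship for jackknife standard errors.
    """

    values: np.ndarray
    per_locus_num: np.ndarray = field(repr=False)  # (n, n, L); NaN = not co-typed
    per_locus_den: np.ndarray = field(repr=False)  # (L,)
    loci: list[str] = field(default_factory=list)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return len(self.per_locus_den)

    def leave_one_locus_out(self, l: int) -> np.ndarray:
        """Multilocus kinship excluding locus ``l``."""
        if self.n_loci < 2:
            raise ValueError("need >=2 loci to jackknife")
        keep = [m for m in range(self.n_loci) if m != l]
        num = np.nansum(self.per_locus_num[:, :, keep], axis=2)
        typed = (~np.isnan(self.per_locus_num[:, :, keep])).any(axis=2)
        den = self.per_locus_den[keep].sum()
        out = num / den
        out[~typed] = np.nan
        return out


def loiselle_kinship(dataset: GenotypeDataset) -> KinshipMatrix:
    """Loiselle et al. (1995) pairwise kinship, referenced to the sample.

    Per locus and allele, the contribution of pair (i, j) is
    ``(x_i - p)(x_j - p) + p(1 - p)/(n - 1)`` where x is the
    individual's allele dosage (0, 1/2 or 1), p the sample frequency and
    n the number of gene copies typed at the locus; the denominator is
    ``sum_a p(1-p)``.  Multilocus values are ratios of summed numerators
    over summed denominators.
    """
    geno = dataset.genotypes
    n, L, _ = geno.shape
    num = np.full((n, n, L), np.nan)
    den = np.zeros(L)
    for l in range(L):
        pair = geno[:, l, :]
        typed = (pair != MISSING).all(axis=1)
        copies = pair[typed].ravel()
        if copies.size == 0:
            continue
        alleles, counts = np.unique(copies, return_counts=True)
        n_copies = copies.size
        p = counts / n_copies
        if len(alleles) < 2:
            den[l] = 0.0
            continue
        # dosage matrix (n, n_alleles) with NaN rows for untyped
        x = np.full((n, len(alleles)), np.nan)
        x[typed] = (
            (pair[typed][:, 0][:, None] == alleles[None, :]).astype(float)
            + (pair[typed][:, 1][:, None] == alleles[None, :]).astype(float)
        ) / 2.0
        dev = x - p[None, :]
        corr = (p * (1 - p) / (n_copies - 1)).sum()
        num[:, :, l] = dev @ dev.T + corr
        den[l] = (p * (1 - p)).sum()
    if den.sum() == 0:
        raise MonomorphicReferenceError("all loci monomorphic in the reference")
    total_num = np.nansum(num, axis=2)
    typed_any = (~np.isnan(num)).any(axis=2)
    values = total_num / den.sum()
    values[~typed_any] = np.nan
    return KinshipMatrix(
        values=values, per_locus_num=num, per_locus_den=den, loci=list(dataset.loci)
    )


def organelle_kinship_analogue(dataset: HaplotypeDataset) -> KinshipMatrix:
    """Distance-based kinship analogue N_ij for a haploid organelle locus.

    Pairwise similarity ``1 - d_ij / d_bar`` where d_bar is the mean
    mutational distance over all distinct pairs in the sample, so the
    all-pairs mean is zero by construction.
    """
    d = dataset.pairwise_individual_distances()
    n = d.shape[0]
    if n < 2:
        raise ValueError("need >=2 individuals")
    iu = np.triu_indices(n, 1)
    d_bar = d[iu].mean()
    if d_bar == 0:
        raise MonomorphicReferenceError("single haplotype in the sample")
    values = 1.0 - d / d_bar
    np.fill_diagonal(values, np.nan)
    num = values[:, :, None].copy()
    return KinshipMatrix(
        values=values, per_locus_num=num, per_locus_den=np.array([1.0]),
        loci=["organelle"],
    )


# ---------------------------------------------------------------------------
# distance classes


def make_distance_classes(
    pair_distances: np.ndarray,
    n_classes: int | None = None,
    min_pairs_per_class: int = 100,
    nn_fraction: float = 0.9,
    nn_distances: np.ndarray | None = None,
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> np.ndarray:
    """Equal-count distance-class upper edges over pairwise distances.

    Quantile bins give near-constant pair counts per class; the first
    edge is then expanded, if needed, so that at least ``nn_fraction``
    of nearest-neighbour distances fall in class 1.  Returns strictly
    increasing upper edges; class c covers ``(edges[c-1], edges[c]]``
    with an implicit lower bound of 0.
    """
    d = np.asarray(pair_distances, dtype=float)
    d = d[(d > 0) & (d <= max_distance)]
    if d.size < 2 * min_pairs_per_class:
        raise ValueError(
            f"only {d.size} pairs within {max_distance} m; need at least "
            f"{2 * min_pairs_per_class} for two classes"
        )
    if n_classes is None:
        n_classes = int(min(10, max(2, d.size // min_pairs_per_class)))
    qs = np.linspace(0, 1, n_classes + 1)[1:]
    edges = np.quantile(d, qs)
    if nn_distances is not None and len(nn_distances):
        nn_edge = float(np.quantile(np.asarray(nn_distances, float), nn_fraction))
        edges[0] = max(edges[0], nn_edge)
    edges[-1] = max(edges[-1], d.max())
    edges = np.unique(edges)
    edges = edges[edges >= edges[0]]
    if len(edges) < 2:
        raise ValueError("degenerate distances: fewer than two distance classes")
    return edges


# ---------------------------------------------------------------------------
# regression


@dataclass
class SgsResults:
    """Kinship-distance regression summary and the Sp statistic."""

    b_ld: float
    r2_ld: float
    se_b: float
    p_perm: float | None
    f_a: float
    sp: float
    class_edges: np.ndarray
    class_table: pd.DataFrame
    n_pairs: int
    n_zero_dropped: int
    n_perm: int
    max_distance: float

    def summary(self) -> str:
        p = "-" if self.p_perm is None else f"{self.p_perm:.4g}"
        return "\n".join(
            [
                "Spatial genetic structure (kinship vs ln distance)",
                "=" * 52,
                f"pairs <= {self.max_distance:g} m: {self.n_pairs} "
                f"(zero-distance pairs dropped: {self.n_zero_dropped})",
                f"b_ld  {self.b_ld: .4f}  (jackknife SE {self.se_b:.4f}, "
                f"R2 {self.r2_ld:.4f})",
                f"permutation p (slope < 0, {self.n_perm} perms): {p}",
                f"F_A   {self.f_a: .4f}   (mean kinship, first class)",
                f"Sp    {self.sp: .4f}   [Sp = -b_ld/(1 - F_A)]",
                "-" * 52,
                self.class_table.round(4).to_string(),
            ]
        )

    def to_dict(self) -> dict:
        return {
            "b_ld": self.b_ld,
            "R2_ld": self.r2_ld,
            "SE_b": self.se_b,
            "p_perm": self.p_perm,
            "F_A": self.f_a,
            "Sp": self.sp,
            "n_pairs": self.n_pairs,
            "n_perm": self.n_perm,
            "max_distance": self.max_distance,
            "class_edges": list(map(float, self.class_edges)),
            "class_table": self.class_table.to_dict(orient="list"),
        }


def _pair_slope(values: np.ndarray, log_d: np.ndarray, mask: np.ndarray):
    f = values[mask]
    x = log_d[mask]
    ok = ~np.isnan(f)
    if ok.sum() < 3 or np.ptp(x[ok]) == 0:
        return np.nan, np.nan
    res = stats.linregress(x[ok], f[ok])
    return res.slope, res.rvalue**2


class KinshipDistanceRegression:
    """Regression of pairwise kinship on ln(geographic distance).

    Parameters
    ----------
    kinship
        A :class:`KinshipMatrix` (nuclear or organelle).
    distances
        ``(n, n)`` pairwise geographic distances in meters.
    class_edges
        Upper edges of the distance classes, or None to build them with
        :func:`make_distance_classes`.
    max_distance
        Pairs beyond this distance (default 10 km) are excluded.
    """

    def __init__(
        self,
        kinship: KinshipMatrix,
        distances: np.ndarray,
        class_edges: np.ndarray | None = None,
        max_distance: float = DEFAULT_MAX_DISTANCE,
        min_pairs_per_class: int = 100,
        nn_fraction: float = 0.9,
    ):
        n = kinship.n_individuals
        distances = np.asarray(distances, dtype=float)
        if distances.shape != (n, n):
            raise ValueError("distance matrix does not match kinship matrix")
        self.kinship = kinship
        self.distances = distances
        self.max_distance = max_distance
        iu = np.triu_indices(n, 1)
        d = distances[iu]
        if class_edges is None:
            nn = np.where(np.eye(n, dtype=bool), np.inf, distances).min(axis=1)
            class_edges = make_distance_classes(
                d,
                min_pairs_per_class=min(min_pairs_per_class, max(2, d.size // 4)),
                nn_fraction=nn_fraction,
                nn_distances=nn[np.isfinite(nn)],
                max_distance=max_distance,
            )
        self.class_edges = np.asarray(class_edges, dtype=float)
        if len(self.class_edges) < 3:
            raise ValueError("need at least three distance classes with data")

    def fit(self, n_perm: int = 10_000, seed: int | None = None) -> SgsResults:
        n = self.kinship.n_individuals
        iu = np.triu_indices(n, 1)
        d = self.distances[iu]
        values = self.kinship.values[iu]
        in_range = (d > 0) & (d <= self.max_distance)
        n_zero = int((d == 0).sum())
        log_d = np.where(in_range, np.log(np.where(d > 0, d, 1.0)), np.nan)

        b, r2 = _pair_slope(values, log_d, in_range)

        # per-class curve
        cls = np.searchsorted(self.class_edges, d[in_range], side="left")
        cls = np.clip(cls, 0, len(self.class_edges) - 1)
        table_rows = []
        for c in range(len(self.class_edges)):
            sel = cls == c
            f = values[in_range][sel]
            dd = d[in_range][sel]
            table_rows.append(
                (
                    self.class_edges[c],
                    int(sel.sum()),
                    float(np.nanmean(dd)) if sel.any() else np.nan,
                    float(np.nanmean(np.log(dd))) if sel.any() else np.nan,
                    float(np.nanmean(f)) if sel.any() and not np.all(np.isnan(f)) else np.nan,
                )
            )
        class_table = pd.DataFrame(
            table_rows,
            columns=[
                "upper_edge_m",
                "n_pairs",
                "mean_dist_m",
                "mean_ln_dist",
                "mean_kinship",
            ],
        )
        classes_with_data = int((class_table["n_pairs"] > 0).sum())
        if classes_with_data < 3:
            raise ValueError("need at least three distance classes with data")
        f_a = float(class_table["mean_kinship"].iloc[0])

        # delete-one-locus jackknife on the slope
        if self.kinship.n_loci >= 2:
            loo = []
            for l in range(self.kinship.n_loci):
                if self.kinship.per_locus_den[l] == 0:
                    continue
                v = self.kinship.leave_one_locus_out(l)[iu]
                loo.append(_pair_slope(v, log_d, in_range)[0])
            loo = np.asarray(loo, dtype=float)
            loo = loo[~np.isnan(loo)]
            k = len(loo)
            se_b = (
                float(np.sqrt((k - 1) / k * ((loo - loo.mean()) ** 2).sum()))
                if k >= 2
                else np.nan
            )
        else:
            se_b = np.nan

        # permutation: shuffle locations among individuals (kinship fixed)
        p_perm = None
        if n_perm:
            rng = np.random.default_rng(seed)
            at_most = 0
            for _ in range(n_perm):
                perm = rng.permutation(n)
                dp = self.distances[np.ix_(perm, perm)][iu]
                in_r = (dp > 0) & (dp <= self.max_distance)
                lp = np.where(in_r, np.log(np.where(dp > 0, dp, 1.0)), np.nan)
                bp, _ = _pair_slope(values, lp, in_r)
                if not np.isnan(bp) and bp <= b:
                    at_most += 1
            p_perm = (1 + at_most) / (n_perm + 1)

        sp = sp_statistic(b, f_a)
        return SgsResults(
            b_ld=float(b),
            r2_ld=float(r2),
            se_b=se_b,
            p_perm=p_perm,
            f_a=f_a,
            sp=sp,
            class_edges=self.class_edges,
            class_table=class_table,
            n_pairs=int(in_range.sum()),
            n_zero_dropped=n_zero,
            n_perm=n_perm,
            max_distance=self.max_distance,
        )


def kinship_distance_regression(
    kinship: KinshipMatrix,
    distances: np.ndarray,
    class_edges: np.ndarray | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
    max_distance: float = DEFAULT_MAX_DISTANCE,
    **kwargs,
) -> SgsResults:
    model = KinshipDistanceRegression(
        kinship, distances, class_edges=class_edges, max_distance=max_distance, **kwargs
    )
    return model.fit(n_perm=n_perm, seed=seed)


def sp_statistic(b_ld: float, f_a: float) -> float:
    """Sp = -b_ld / (1 - F_A); undefined when F_A >= 1."""
    if f_a >= 1:
        raise ValueError("F_A must be below 1")
    return -b_ld / (1.0 - f_a)
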