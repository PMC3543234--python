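"""Loiselle kinship, distance classes, kinship-distance regression, Sp."""

import numpy as np
import pytest

from pollenseed.datasets import GenotypeDataset, HaplotypeDataset
from pollenseed.sgs import (
    KinshipDistanceRegression,
    KinshipMatrix,
    MonomorphicReferenceError,
    loiselle_kinship,
    make_distance_classes,
    organelle_kinship_analogue,
    sp_statistic,
)

from ._oracles import loiselle_oracle
from .conftest import make_genotype_dataset


class TestLoiselleKinship:
    def test_four_individual_toy_exact(self):
        # one biallelic locus, genotypes AA, AB, BB, AB with p = 1/2:
        # F(1,3) = -6/7 and every other pair 1/7 (worked by hand from
        # the sum-over-alleles definition with the p(1-p)/(n-1) term)
        geno = np.array([[[1, 1]], [[1, 2]], [[2, 2]], [[1, 2]]])
        ds = GenotypeDataset(["a", "b", "c", "d"], ["p"] * 4, ["L0"], geno)
        kin = loiselle_kinship(ds)
        assert kin.values[0, 2] == pytest.approx(-6 / 7, abs=1e-12)
        for i, j in [(0, 1), (0, 3), (1, 2), (1, 3), (2, 3)]:
            assert kin.values[i, j] == pytest.approx(1 / 7, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ds = make_genotype_dataset(
            rng, n_pops=1, n_per_pop=8, n_loci=3, n_alleles=3, missing_rate=0.1
        )
        kin = loiselle_kinship(ds)
        oracle = loiselle_oracle(ds.genotypes)
        assert np.allclose(kin.values, oracle, atol=1e-12, equal_nan=True)

    def test_sample_mean_near_zero(self, rng):
        # centering on the sample's own frequencies forces the all-pairs
        # mean toward zero; the residual is O(1/n^2) under random mating
        ds = make_genotype_dataset(rng, n_pops=1, n_per_pop=60, n_loci=6)
        kin = loiselle_kinship(ds)
        iu = np.triu_indices(ds.n_individuals, 1)
        assert abs(np.nanmean(kin.values[iu])) < 2.0 / ds.n_individuals

    def test_clonal_pair_exceeds_mean(self, rng):
        ds = make_genotype_dataset(rng, n_pops=1, n_per_pop=20, n_loci=5)
        geno = ds.genotypes.copy()
        geno[1] = geno[0]  # duplicate individual 0's multilocus genotype
        ds2 = GenotypeDataset(ds.individual_id, ds.population, ds.loci, geno)
        kin = loiselle_kinship(ds2)
        iu = np.triu_indices(20, 1)
        assert kin.values[0, 1] > np.nanmean(kin.values[iu])

    def test_monomorphic_reference_raises(self):
        geno = np.full((4, 2, 2), 5)
        ds = GenotypeDataset(["a", "b", "c", "d"], ["p"] * 4, ["L0", "L1"], geno)
        with pytest.raises(MonomorphicReferenceError):
            loiselle_kinship(ds)


class TestOrganelleKinshipAnalogue:
    def _three_hap(self):
        dist = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        return HaplotypeDataset(
            ["a", "b", "c"], ["p"] * 3, np.array([1, 2, 3]), dist
        )

    def test_hand_computed_values(self):
        # distances {1, 2, 3}, mean 2 -> N = 1 - d/2: 0.5, 0.0, -0.5
        kin = organelle_kinship_analogue(self._three_hap())
        assert kin.values[0, 1] == pytest.approx(0.5)
        assert kin.values[0, 2] == pytest.approx(0.0)
        assert kin.values[1, 2] == pytest.approx(-0.5)

    def test_all_pairs_mean_zero(self):
        kin = organelle_kinship_analogue(self._three_hap())
        iu = np.triu_indices(3, 1)
        assert np.nanmean(kin.values[iu]) == pytest.approx(0.0, abs=1e-12)

    def test_identical_haplotypes_maximal(self):
        dist = np.array([[0, 2], [2, 0]])
        hs = HaplotypeDataset(
            ["a", "b", "c"], ["p"] * 3, np.array([1, 1, 2]), dist
        )
        kin = organelle_kinship_analogue(hs)
        iu = np.triu_indices(3, 1)
        assert kin.values[0, 1] == np.nanmax(kin.values[iu])

    def test_monomorphic_raises(self):
        hs = HaplotypeDataset(
            ["a", "b"], ["p"] * 2, np.array([1, 1]), np.zeros((1, 1), int)
        )
        with pytest.raises(MonomorphicReferenceError):
            organelle_kinship_analogue(hs)


class TestDistanceClasses:
    def test_equal_counts_before_nn_adjustment(self, rng):
        d = rng.uniform(1, 5000, 4000)
        edges = make_distance_classes(d, n_classes=10, min_pairs_per_class=100)
        cls = np.clip(np.searchsorted(edges, d, side="left"), 0, len(edges) - 1)
        counts = np.bincount(cls, minlength=len(edges))
        assert counts.max() - counts.min() <= 2

    def test_first_class_covers_nearest_neighbours(self, rng):
        # clustered transect: tight clumps spread along a line
        centers = rng.uniform(0, 10_000, 20)
        pts = np.concatenate([c + rng.uniform(0, 5, 10) for c in centers])
        D = np.abs(pts[:, None] - pts[None, :])
        iu = np.triu_indices(len(pts), 1)
        nn = np.where(np.eye(len(pts), dtype=bool), np.inf, D).min(axis=1)
        edges = make_distance_classes(
            D[iu], min_pairs_per_class=50, nn_distances=nn, nn_fraction=0.9
        )
        assert (nn <= edges[0]).mean() >= 0.9

    def test_equidistant_pairs_degenerate(self):
        with pytest.raises(ValueError):
            make_distance_classes(np.full(500, 100.0), min_pairs_per_class=50)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="two classes"):
            make_distance_classes(np.array([1.0, 2.0, 3.0]), min_pairs_per_class=100)


def _synthetic_kinship(n, a, b, coords_scale=1000.0, seed=0):
    """KinshipMatrix with F_ij = a + b ln(d_ij) exactly (one locus)."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(1.0, coords_scale, n)
    D = np.abs(x[:, None] - x[None, :])
    D[D == 0] = 1.0
    np.fill_diagonal(D, 0.0)
    values = a + b * np.log(np.where(D > 0, D, 1.0))
    np.fill_diagonal(values, np.nan)
    kin = KinshipMatrix(
        values=values,
        per_locus_num=values[:, :, None].copy(),
        per_locus_den=np.array([1.0]),
        loci=["synthetic"],
    )
    return kin, D


class TestRegression:
    def test_recovers_linear_relation_exactly(self):
        kin, D = _synthetic_kinship(40, a=0.05, b=-0.012)
        res = KinshipDistanceRegression(kin, D, max_distance=1e9).fit(n_perm=0)
        assert res.b_ld == pytest.approx(-0.012, abs=1e-12)
        assert res.r2_ld == pytest.approx(1.0, abs=1e-12)

    def test_spatially_random_slope_null(self, rng):
        ds = make_genotype_dataset(rng, n_pops=1, n_per_pop=80, n_loci=6)
        kin = loiselle_kinship(ds)
        x = rng.uniform(0, 5000, 80)
        D = np.abs(x[:, None] - x[None, :])
        res = KinshipDistanceRegression(kin, D).fit(n_perm=199, seed=3)
        assert abs(res.b_ld) < 0.02
        assert res.p_perm > 0.01

    def test_jackknife_zero_when_loci_identical(self):
        kin, D = _synthetic_kinship(30, a=0.02, b=-0.008)
        num = np.repeat(kin.per_locus_num, 4, axis=2)
        kin4 = KinshipMatrix(
            values=kin.values,
            per_locus_num=num,
            per_locus_den=np.ones(4),
            loci=[f"L{i}" for i in range(4)],
        )
        # identical per-locus signal -> every leave-one-out slope equal
        res = KinshipDistanceRegression(kin4, D, max_distance=1e9).fit(n_perm=0)
        assert res.se_b == pytest.approx(0.0, abs=1e-12)

    def test_class_mean_regression_agrees_on_homogeneous_classes(self):
        # when kinship is exactly linear in ln d, the pair-level slope
        # equals the count-weighted regression on class means
        kin, D = _synthetic_kinship(40, a=0.05, b=-0.012)
        res = KinshipDistanceRegression(kin, D, max_distance=1e9).fit(n_perm=0)
        tab = res.class_table.dropna()
        w = tab["n_pairs"].to_numpy(float)
        x = tab["mean_ln_dist"].to_numpy()
        y = tab["mean_kinship"].to_numpy()
        # exact linearity makes the within-class scatter fall on the same
        # line, so the count-weighted class-mean slope equals the pair slope
        xbar = (w * x).sum() / w.sum()
        ybar = (w * y).sum() / w.sum()
        slope = (w * (x - xbar) * (y - ybar)).sum() / (w * (x - xbar) ** 2).sum()
        assert slope == pytest.approx(res.b_ld, abs=1e-9)

    def test_zero_distance_pairs_dropped(self):
        kin, D = _synthetic_kinship(30, a=0.02, b=-0.01)
        D[0, 1] = D[1, 0] = 0.0
        res = KinshipDistanceRegression(kin, D, max_distance=1e9).fit(n_perm=0)
        assert res.n_zero_dropped == 1


class TestSpStatistic:
    @pytest.mark.parametrize(
        "b,fa,expected",
        [
            (-0.0217, 0.144, 0.025),
            (-0.0308, 0.139, 0.036),
            (-0.0095, 0.043, 0.010),
            (0.0, 0.3, 0.0),
        ],
    )
    def test_values(self, b, fa, expected):
        assert round(sp_statistic(b, fa), 3) == pytest.approx(expected)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            sp_statistic(-0.01, 1.0)

    def test_definition_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            b = rng.uniform(-0.1, 0.0)
            fa = rng.uniform(-0.2, 0.9)
            assert sp_statistic(b, fa) == -b / (1 - fa)
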