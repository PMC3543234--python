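"""Forward-time simulator of hermaphroditic plant metapopulations with
mixed mating and decoupled pollen/seed dispersal.

Life cycle (non-overlapping generations, constant deme sizes):

1. *Seed migration* — each offspring slot in deme k draws its mother
   from deme k with probability ``1 - m_seed``, otherwise uniformly from
   another deme.  The seed carries the full diploid zygote plus the
   maternal organelle, so seed movement moves two nuclear copies and
   the haplotype.
2. *Mating* — with probability ``selfing`` the offspring is selfed
   (both gametes from the mother); otherwise the pollen parent comes
   from the mother's deme with probability ``1 - m_pollen``, else from
   another deme.  Pollen moves exactly one outcrossed nuclear gamete
   and never the organelle.
3. *Mutation* — microsatellites mutate stepwise (allele +/- 1 repeat,
   reflecting at 1) at ``mu_nuc`` per copy per generation; the
   organelle mutates to a fresh haplotype (infinite alleles) at
   ``mu_org``.

``linear`` spatial mode replaces deme draws with Gaussian dispersal
kernels of scale ``sigma_seed`` / ``sigma_pollen`` over fixed sites on
a 1-D habitat, producing isolation by distance; sites keep planar
coordinates in meters.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .datasets import MISSING, GenotypeDataset, HaplotypeDataset

__all__ = ["SimConfig", "SimOutput", "simulate", "inject_null_alleles"]


@dataclass
class SimConfig:
    """Simulation parameters; defaults give a desk-scale island model."""

    n_demes: int = 4
    deme_size: int = 100
    generations: int = 200
    selfing: float = 0.0
    m_pollen: float = 0.01
    m_seed: float = 0.01
    n_loci: int = 10
    mu_nuc: float = 1e-3
    mu_org: float = 1e-3
    spatial_mode: str = "island"
    sigma_seed: float = 50.0
    sigma_pollen: float = 50.0
    habitat_length: float = 5000.0
    q_null: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("selfing", "m_pollen", "m_seed", "mu_nuc", "mu_org", "q_null"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.q_null >= 1.0 and self.q_null != 0.0:
            raise ValueError("q_null must lie in [0, 1)")
        if self.deme_size < 2:
            raise ValueError("deme_size must be >= 2")
        if self.n_demes < 1 or self.n_loci < 1 or self.generations < 0:
            raise ValueError("n_demes, n_loci positive; generations non-negative")
        if self.spatial_mode not in ("island", "linear"):
            raise ValueError("spatial_mode must be 'island' or 'linear'")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimOutput:
    """Simulated datasets plus the generating parameters."""

    genotypes: GenotypeDataset
    haplotypes: HaplotypeDataset
    config: SimConfig
    truth: dict = field(default_factory=dict)


def _categorical_rows(cum_weights: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Draw one index per row from row-wise cumulative weights."""
    return (cum_weights < u[:, None]).sum(axis=1)


def simulate(config: SimConfig) -> SimOutput:
    rng = np.random.default_rng(config.seed)
    n_demes, N, L = config.n_demes, config.deme_size, config.n_loci
    n_tot = n_demes * N
    deme = np.repeat(np.arange(n_demes), N)

    geno = rng.integers(95, 106, size=(n_tot, L, 2))
    org = deme.copy() + 1
    next_hap = n_demes + 1

    linear = config.spatial_mode == "linear"
    if linear:
        x = np.sort(rng.uniform(0.0, config.habitat_length, size=n_tot))
        # fixed sites: precompute cumulative dispersal kernels
        d2 = (x[:, None] - x[None, :]) ** 2
        k_seed = np.exp(-d2 / (2 * config.sigma_seed**2))
        k_pollen = np.exp(-d2 / (2 * config.sigma_pollen**2))
        # outcrossed pollen never comes from the mother herself; selfing
        # is governed exclusively by the selfing parameter
        np.fill_diagonal(k_pollen, 0.0)
        cum_seed = np.cumsum(k_seed, axis=1)
        cum_seed /= cum_seed[:, -1:]
        cum_pollen = np.cumsum(k_pollen, axis=1)
        cum_pollen /= cum_pollen[:, -1:]
    else:
        x = None

    for _ in range(config.generations):
        if linear:
            mother = _categorical_rows(cum_seed, rng.random(n_tot))
            father = _categorical_rows(cum_pollen[mother], rng.random(n_tot))
        else:
            # seed migration: mother's deme
            mdeme = deme.copy()
            if n_demes > 1:
                mig = rng.random(n_tot) < config.m_seed
                shift = rng.integers(1, n_demes, size=int(mig.sum()))
                mdeme[mig] = (deme[mig] + shift) % n_demes
            mother = mdeme * N + rng.integers(0, N, size=n_tot)
            # pollen migration: father's deme relative to the mother's
            fdeme = mdeme.copy()
            pmig = rng.random(n_tot) < config.m_pollen
            if n_demes > 1:
                shift = rng.integers(1, n_demes, size=pmig.sum())
                fdeme[pmig] = (mdeme[pmig] + shift) % n_demes
            father = fdeme * N + rng.integers(0, N, size=n_tot)
            # an outcrossed father must differ from the mother (selfing is
            # handled separately below); redraw within the same deme
            clash = father == mother
            while clash.any():
                father[clash] = fdeme[clash] * N + rng.integers(
                    0, N, size=int(clash.sum())
                )
                clash = father == mother

        selfed = rng.random(n_tot) < config.selfing
        father = np.where(selfed, mother, father)

        pick_m = rng.integers(0, 2, size=(n_tot, L))
        pick_f = rng.integers(0, 2, size=(n_tot, L))
        li = np.broadcast_to(np.arange(L)[None, :], (n_tot, L))
        child = np.empty_like(geno)
        child[:, :, 0] = geno[mother[:, None], li, pick_m]
        child[:, :, 1] = geno[father[:, None], li, pick_f]

        # stepwise mutation, reflecting at repeat size 1
        mut = rng.random(child.shape) < config.mu_nuc
        step = rng.choice((-1, 1), size=child.shape)
        child = np.where(mut, child + step, child)
        child[child < 1] = 2

        org = org[mother]
        omut = rng.random(n_tot) < config.mu_org
        n_new = int(omut.sum())
        if n_new:
            org = org.copy()
            org[omut] = np.arange(next_hap, next_hap + n_new)
            next_hap += n_new

        geno = child

    # canonical haplotype ids by first occurrence
    _, first = np.unique(org, return_index=True)
    order = {org[i]: rank + 1 for rank, i in enumerate(np.sort(first))}
    hap_ids = np.array([order[h] for h in org])
    k = len(order)
    dist = np.ones((k, k), dtype=np.int64) - np.eye(k, dtype=np.int64)

    ids = [f"ind{i + 1}" for i in range(n_tot)]
    if linear:
        pops = ["pop1"] * n_tot
        seg = np.minimum(
            (x / config.habitat_length * n_demes).astype(int), n_demes - 1
        )
        subpop = [f"deme{s + 1}" for s in seg]
        coords = np.column_stack([x, np.zeros(n_tot)])
        units = "meters"
    else:
        pops = [f"deme{d + 1}" for d in deme]
        subpop = None
        coords = None
        units = None

    genotypes = GenotypeDataset(
        individual_id=ids,
        population=pops,
        loci=[f"locus{l + 1}" for l in range(L)],
        genotypes=geno,
        subpopulation=subpop,
        coords=coords,
        coord_units=units,
    )
    # the haplotype table is grouped at the finest spatial level: demes in
    # island mode, habitat segments in linear mode
    haplotypes = HaplotypeDataset(
        individual_id=ids,
        population=subpop if linear else pops,
        haplotype_id=hap_ids,
        distance_matrix=dist,
    )
    s = config.selfing
    truth = {
        **config.to_dict(),
        "expected_fis": s / (2.0 - s),
        "expected_outcrossing": 1.0 - s,
        "n_haplotypes": k,
    }
    if config.q_null > 0:
        genotypes, realized = inject_null_alleles(
            genotypes, config.q_null, seed=rng.integers(2**31), return_realized=True
        )
        truth["realized_null_frequency"] = realized
    return SimOutput(
        genotypes=genotypes, haplotypes=haplotypes, config=config, truth=truth
    )


def inject_null_alleles(
    dataset: GenotypeDataset,
    q_null: float,
    seed: int | None = None,
    return_realized: bool = False,
):
    """Mask a random set of allele lineages per locus as nulls.

    Allele states are added to the null set in random order until their
    combined frequency is as close as possible to ``q_null`` (the last
    allele is kept only if it improves the match).  A heterozygote with
    one null copy appears homozygous for the visible allele; null/null
    genotypes become missing — exactly the footprint the Brookfield
    method-1 estimator is built to detect.
    """
    if not (0.0 <= q_null < 1.0):
        raise ValueError("q_null must lie in [0, 1)")
    if q_null == 0.0:
        return (dataset, {}) if return_realized else dataset
    rng = np.random.default_rng(seed)
    geno = dataset.genotypes.copy()
    realized: dict[str, float] = {}
    for l, locus in enumerate(dataset.loci):
        copies = geno[:, l, :].ravel()
        copies = copies[copies != MISSING]
        alleles, counts = np.unique(copies, return_counts=True)
        freqs = counts / counts.sum()
        order = rng.permutation(len(alleles))
        null_set: list[int] = []
        cum = 0.0
        for a in order:
            if cum >= q_null:
                break
            if abs(cum + freqs[a] - q_null) <= abs(cum - q_null):
                null_set.append(int(alleles[a]))
                cum += freqs[a]
        realized[locus] = float(cum)
        if not null_set:
            continue
        is_null = np.isin(geno[:, l, :], null_set)
        both = is_null.all(axis=1)
        geno[both, l, :] = MISSING
        one = is_null.any(axis=1) & ~both
        visible = np.where(is_null[one, 0], geno[one, l, 1], geno[one, l, 0])
        geno[one, l, 0] = visible
        geno[one, l, 1] = visible
    out = GenotypeDataset(
        individual_id=list(dataset.individual_id),
        population=list(dataset.population),
        loci=list(dataset.loci),
        genotypes=geno,
        subpopulation=None
        if dataset.subpopulation is None
        else list(dataset.subpopulation),
        coords=None if dataset.coords is None else dataset.coords.copy(),
        coord_units=dataset.coord_units,
    )
    return (out, realized) if return_realized else out
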