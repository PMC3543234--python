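# Methods

This note records the statistical models implemented in `pollenseed`,
the conventions and numerical choices behind them, what the forward
simulator does and does not emulate, and the package's known
limitations.

## Data model

Diploid genotypes are integer allele pairs per locus (`0` = missing); a
genotype is whole-locus missing or fully typed — half calls are
rejected, matching microsatellite scoring practice, and nothing is
imputed. Organelle haplotypes are small integer ids with a symmetric
matrix of mutational differences. Aligned FASTA input is collapsed into
haplotypes after *complete-column deletion* (any column containing a
gap or non-ACGT symbol in any sequence is dropped globally), so the
resulting distances form a true Hamming metric; pairwise deletion would
not. Geographic distances use the haversine formula on a 6,371,000 m
sphere for latitude/longitude input (spherical error is negligible at
the ≤300 km scales this package targets) and planar Euclidean distance
for metric coordinates.

## Nuclear F-statistics

F_IS and F_ST are Weir & Cockerham's (1984) f and θ, assembled from the
among-population (a), among-individual (b) and within-individual (c)
variance components summed over alleles and loci:
θ = Σa / Σ(a+b+c), f = Σb / Σ(b+c). Multilocus estimates are ratios of
summed components, never means of per-locus ratios. Standard errors are
delete-one-locus jackknives, SE² = (L−1)/L · Σ(θ₍₋ᵢ₎ − θ̄₍₋₎)². Missing
data are handled per locus by complete-case exclusion within each
population. The estimators are validated against an independent
sums-of-squares (mean-squares) implementation on randomized tiny
instances to 1e-9.

Pairwise F_ST uses the same θ per population pair; significance comes
from permuting individuals between the two populations, with the
observed statistic included in the reference set:
p = (1 + #{θ* ≥ θ}) / (n_perm + 1), so p ∈ (0, 1]. Permutations of a
discrete configuration can tie the observed statistic (e.g. the mirror
split of two fixed populations), so the smallest achievable p is not
always 1/(n_perm+1).

The equilibrium outcrossing rate inverts the mixed-mating equilibrium
F = (1−t)/(1+t): t = (1 − F_IS)/(1 + F_IS), reported clamped to [0, 1]
when F_IS ∈ [0, 1]. Brookfield's method-1 null-allele frequency is
q̂ = (H_e − H_o)/(1 + H_e), with heterozygote excess passed through as a
negative value (see Limitations for this estimator's bias).

## AMOVA

One hierarchical level (among vs. within populations), the classic
squared-distance ANOVA. For nuclear data the units are gene copies (two
per individual; phase is irrelevant to the sums) and the squared
distance between copies is the number of loci at which they differ —
the allele-identity ("F_ST-based") choice; repeat-size R_ST distances
are deliberately not offered. For haplotypes the units are individuals
and the squared distance is the squared number of differing sites.
Variance components use the unequal-sample-size coefficient
n_c = (N − ΣN_k²/N)/(G−1); Φ_ST = σ²_a/(σ²_a+σ²_w). A negative σ²_a is
reported as estimated, with the percentage display floored at zero.
Permutations move whole individuals among populations (a diploid's two
copies travel together), 10,000 by default. With identity distances on
haploid data the machinery reduces exactly to the Weir–Cockerham
haploid θ, which the tests verify against an independent ANOVA oracle.

## Spatial genetic structure

Pairwise kinship is the Loiselle et al. (1995) estimator referenced to
the analysed sample itself: per locus and allele the pair contribution
is (x_i − p)(x_j − p) + p(1−p)/(n−1), with x the dosage (0, ½, 1), p
the sample frequency and n the number of typed gene copies; the
denominator is Σ_a p(1−p), and multilocus kinship is the ratio of
summed numerators over summed denominators. Centering on the sample
forces the all-pairs mean toward zero; the between-individual residual
is O(1/n²), not exactly zero. The organelle analogue N_ij is the
distance-based haploid similarity 1 − d_ij/d̄, which is mean-zero by
construction.

Distance classes are equal-count quantile bins of the pairwise
distances (constant pair numbers per class); the first edge is then
expanded, if necessary, until at least 90% of nearest-neighbour
distances fall in class 1, so F_A — the mean kinship in the first class
— really is a nearest-neighbour quantity.

The slope b_ld is the OLS regression of pairwise kinship on
ln(distance) over *individual pairs* (class means are reported for the
autocorrelogram output; when kinship is exactly linear in ln d the
count-weighted class-mean regression gives the same slope). Pairs
beyond 10 km are excluded by default; co-located pairs (d = 0) are
excluded from the regression and counted in the results. The SE of
b_ld is a delete-one-locus jackknife on the multilocus kinship;
significance comes from shuffling spatial locations among individuals,
one-sided for a negative slope since restricted dispersal predicts
kinship decline. Finally Sp = −b_ld / (1 − F_A). Where a deme column is
provided, per-deme reruns simply subset the table; admixture flagging
is an input, not something this package infers.

## Organelle diversity and structure

H_d is Nei's unbiased haplotype diversity n/(n−1)(1 − Σp²). G_ST uses
unbiased within-population diversities (sample-size-weighted mean) and
the pooled-frequency total diversity with the same unbiased correction.
Because the organelle is a single linked locus, a locus jackknife is
impossible; the SE is a delete-one-population jackknife instead (it
therefore needs at least three populations, and reflects among-
population heterogeneity rather than marker sampling). Confidence
intervals are estimate ± 2 SE and may exceed [0, 1].

## Pollen vs. seed inference

Under equal pollen and seed migration, the maternal marker's expected
differentiation follows from the ratio of effective numbers of the two
genomes: F_ST(mat) = a_b F_b / (a_m + (a_b − a_m) F_b) with a_m = 2 for
a haploid uniparental genome and a_b = 4 + 2t for a diploid biparental
genome whose effective size grows with the outcrossing rate t (at t = 1,
a_b = 6 = 3 × 2: three genome copies move per seed+pollen event for
every organelle copy). This coefficient reproduces the published
two-species table to four decimals in both rows. The test's intervals
are ±2 SE: the expected value keeps the *nuclear* F_ST half-width
(the transformation's point estimate is moved, its uncertainty is not
re-propagated), the observed value uses the G_ST SE; H0 is rejected only
if the closed intervals are disjoint.

The Ennos ratio r = [(1/F_b − 1)(1 + F_IS) − 2(1/G_m − 1)]/(1/G_m − 1)
estimates m_p/m_s. Two internal properties worth knowing: r is strictly
*increasing* in G_m (more maternal structure ⇒ relatively less seed
flow), and when G_m equals the equal-migration expectation above, r
evaluates to 1 + F_IS rather than exactly 1 — a mild tension between
the two formulations that should be kept in mind when reading r near
the null. The model object clamps t to [0, 1] before the expectation,
since sampling-noise negative F_IS would otherwise imply t > 1.

Rounding conventions follow the field's tables — four decimals for
F/G-statistics and t, two for r, three for Sp — and are applied only at
the presentation layer; JSON outputs carry full precision.

## Forward simulator

Non-overlapping generations, constant deme sizes (soft selection),
hermaphrodites. Each offspring slot draws a mother (seed migration
m_s: stay with probability 1−m_s, else a uniform other deme), selfs
with probability s, otherwise draws a pollen parent (pollen migration
m_p relative to the mother's deme) that is never the mother herself —
so the selfing parameter alone controls selfing, and equilibrium
F_IS = s/(2−s) is recovered without the 1/N bias that self-compatible
random draws would add. The seed carries the zygote and the maternal
organelle; pollen carries one gamete. Microsatellites mutate stepwise
(±1 repeat, reflecting at 1) at mu_nuc = 1e-3 per copy per generation;
the organelle mutates to a fresh haplotype (infinite alleles) at
mu_org = 1e-3 — few haplotypes, small network distances, which is why
identity distances are attached to simulated haplotype sets. Linear
mode fixes sites on a 1-D habitat and replaces deme draws with Gaussian
dispersal kernels (σ_seed, σ_pollen), producing isolation by distance
with planar coordinates.

Defaults (4 demes × 100 diploids, 200 generations, 10 loci,
m_p = m_s = 0.01, no selfing) run in well under a second and sit near
migration-drift equilibrium. Null-allele injection masks a random set
of allele lineages per locus whose combined frequency approximates the
target: a heterozygote with one null appears homozygous, null/null
becomes missing; the realized masked frequency per locus is returned on
request.

What the simulator does *not* emulate: overlapping generations,
selection, realistic estuary geometry or ocean-current asymmetries,
genotyping error other than null alleles, and sequence-level organelle
evolution (haplotypes are exchangeable labels). Passing the recovery
tests therefore shows the estimators are correct under the island/
lattice models they assume — not that those models describe any
particular field system.

## Validation scale

The test suite validates at desk scale, chosen to keep the full run
around a minute: mating-system equilibria use 12 replicates of
2 demes × 50 over 100 generations (assertion within 3 Monte-Carlo SEs
of s/(2−s)); the organelle-vs-nuclear differentiation contrast uses 20
replicates at the default configuration; Ennos-ratio rank recovery uses
8 demes × 100 with migration pairs (0.02, 0.08), (0.04, 0.04),
(0.08, 0.02) and 20 replicates per point; isolation-by-distance slope
significance uses 20 linear-habitat replicates (σ = 100 m over 5 km,
99 permutations, one-sided p < 0.05); permutation-uniformity checks use
200 null replicates at 99 permutations (Kolmogorov–Smirnov).

## Limitations

- **Brookfield method 1 is a small-q approximation.** Under the masking
  model (heterozygote with one null scored homozygous, null/null
  missing) the apparent allele frequencies stay proportional to the
  visible ones, giving E[H_e − H_o] = H_e · 2q/(1+q) and hence
  E[q̂] ≈ 2q·H_e/((1+q)(1+H_e)): accurate for q ≲ 0.05, but
  substantially below q at q ≈ 0.2 (the simulation tests confirm the
  analytic expectation). The formula is kept because it is the field's
  reporting convention; treat large estimates as lower bounds.
- The G_ST standard error is a population jackknife (see above), an
  assumption forced by the single-locus organelle data.
- The pollen/seed formulas assume island-model equilibrium and ignore
  mutation; with migration rates within an order of magnitude of the
  mutation rate, r inherits a bias.
- One AMOVA level only; nested (ocean/estuary/individual) designs are
  out of scope.
- Permutation p-values are valid but discrete; with few exchangeable
  units or heavily tied statistics they are conservative.
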