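"""Data model, readers/writers, haplotype collapsing, geographic distances."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pollenseed.datasets import (
    DataFormatError,
    GenotypeDataset,
    HaplotypeDataset,
)
from pollenseed.io import (
    collapse_fasta_to_haplotypes,
    pairwise_geographic_distance,
    read_genotype_table,
    write_genotype_table,
)


def test_genepop_three_digit_parsing(tmp_path):
    p = tmp_path / "toy.gen"
    p.write_text("toy\nlocus1\nlocus2\nPOP\nind1 , 092092 110112\n")
    ds = read_genotype_table(p, dialect="genepop")
    assert ds.individual_id == ["ind1"]
    assert ds.loci == ["locus1", "locus2"]
    assert ds.genotypes[0, 0].tolist() == [92, 92]
    assert sorted(ds.genotypes[0, 1].tolist()) == [110, 112]


def test_genepop_missing_and_two_digit(tmp_path):
    p = tmp_path / "toy.gen"
    p.write_text("toy\nL1, L2\nPOP\na , 0102 0000\nPOP\nb , 0202 0101\n")
    ds = read_genotype_table(p, dialect="genepop")
    assert ds.population == ["pop1", "pop2"]
    assert ds.genotypes[0, 1].tolist() == [0, 0]
    assert ds.missing_mask()[0, 1]


def test_csv_missing_genotype(tmp_path):
    p = tmp_path / "toy.csv"
    p.write_text("id,pop,L1_1,L1_2,L2_1,L2_2\nA,x,1,2,NA,NA\nB,x,2,2,3,3\n")
    ds = read_genotype_table(p, dialect="csv")
    assert ds.missing_mask()[0, 1] and not ds.missing_mask()[0, 0]


@pytest.mark.parametrize(
    "content,match",
    [
        ("id,pop,L1_1\nA,x,1\n", "odd number"),
        ("id,pop,L1_1,L1_2\nA,x,1,2\nA,x,2,2\n", "duplicate"),
        ("id,pop,L1_1,L1_2\nA,x,foo,2\n", "unparseable"),
        ("id,pop,L1_1,L1_2\nA,x,,2\n", "half-missing"),
    ],
)
def test_csv_format_errors(tmp_path, content, match):
    p = tmp_path / "bad.csv"
    p.write_text(content)
    with pytest.raises(DataFormatError, match=match):
        read_genotype_table(p, dialect="csv")


@st.composite
def genotype_datasets(draw):
    n_pops = draw(st.integers(1, 3))
    n_per = draw(st.integers(1, 4))
    n_loci = draw(st.integers(1, 3))
    n = n_pops * n_per
    rng = np.random.default_rng(draw(st.integers(0, 2**31 - 1)))
    geno = rng.integers(1, 999, size=(n, n_loci, 2))
    miss = rng.random((n, n_loci)) < 0.15
    geno[miss] = 0
    with_coords = draw(st.booleans())
    units = draw(st.sampled_from(["degrees", "meters"])) if with_coords else None
    coords = (
        np.round(rng.uniform(-10, 10, size=(n, 2)), 6) if with_coords else None
    )
    return GenotypeDataset(
        individual_id=[f"ind{i}" for i in range(n)],
        population=[f"pop{i // n_per + 1}" for i in range(n)],
        loci=[f"L{l}" for l in range(n_loci)],
        genotypes=geno,
        coords=coords,
        coord_units=units,
    )


@given(genotype_datasets(), st.sampled_from(["csv", "genepop"]))
def test_round_trip_is_lossless(tmp_path_factory, ds, dialect):
    path = tmp_path_factory.mktemp("rt") / f"ds.{dialect}"
    write_genotype_table(ds, path, dialect=dialect)
    back = read_genotype_table(path, dialect=dialect)
    if dialect == "genepop":
        # GENEPOP carries no coordinates; pop labels are positional
        assert back.individual_id == ds.individual_id
        assert back.loci == ds.loci
        assert np.array_equal(back.genotypes, ds.genotypes)
        assert back.population == ds.population
    else:
        assert back.equals(ds)


def test_allele_frequencies_sum_to_one(small_dataset):
    table = small_dataset.allele_frequencies()
    checked = 0
    for key, freqs in table.frequencies.items():
        if table.n_copies[key] > 0:
            assert abs(sum(freqs.values()) - 1.0) < 1e-9
            checked += 1
    assert checked > 0


def test_monomorphic_locus_single_frequency():
    ds = GenotypeDataset(
        ["a", "b"], ["p", "p"], ["L1"], np.full((2, 1, 2), 7, dtype=int)
    )
    assert ds.allele_frequencies().frequencies[("p", "L1")] == {7: 1.0}


# ---------------------------------------------------------------------------
# FASTA haplotype collapsing


def _write_fasta(path, records):
    path.write_text("".join(f">{name}\n{seq}\n" for name, seq in records))


def test_identical_sequences_collapse_to_one_haplotype(tmp_path):
    f = tmp_path / "a.fa"
    _write_fasta(f, [("s1", "ACGT"), ("s2", "ACGT")])
    hs = collapse_fasta_to_haplotypes(f, {"s1": "p", "s2": "p"})
    assert hs.n_haplotypes == 1
    assert hs.distance_matrix.tolist() == [[0]]


def test_single_difference_two_haplotypes(tmp_path):
    f = tmp_path / "a.fa"
    _write_fasta(f, [("s1", "ACGT"), ("s2", "ACCT")])
    hs = collapse_fasta_to_haplotypes(f, {"s1": "p", "s2": "p"})
    assert hs.n_haplotypes == 2
    assert hs.distance_matrix[0, 1] == 1


def test_gap_column_dropped_globally(tmp_path):
    # the gapped column is removed for everyone, leaving identical strings
    f = tmp_path / "a.fa"
    _write_fasta(f, [("s1", "AC-T"), ("s2", "ACTT")])
    hs = collapse_fasta_to_haplotypes(f, {"s1": "p", "s2": "p"})
    assert hs.n_haplotypes == 1
    assert np.array_equal(hs.haplotype_id, [1, 1])


def test_unequal_lengths_rejected(tmp_path):
    f = tmp_path / "a.fa"
    _write_fasta(f, [("s1", "ACGT"), ("s2", "ACG")])
    with pytest.raises(DataFormatError, match="aligned"):
        collapse_fasta_to_haplotypes(f, {"s1": "p", "s2": "p"})


def test_haplotype_ids_invariant_to_input_order(tmp_path):
    recs = [("s1", "ACGT"), ("s2", "ACCT"), ("s3", "ACGT"), ("s4", "TCGT")]
    pops = {n: "p" for n, _ in recs}
    f1, f2 = tmp_path / "f1.fa", tmp_path / "f2.fa"
    _write_fasta(f1, recs)
    _write_fasta(f2, recs[::-1])
    h1 = collapse_fasta_to_haplotypes(f1, pops)
    h2 = collapse_fasta_to_haplotypes(f2, pops)
    # same partition of sequences into haplotypes, ids by first occurrence
    part1 = {n: h for n, h in zip(h1.individual_id, h1.haplotype_id)}
    part2 = {n: h for n, h in zip(h2.individual_id, h2.haplotype_id)}
    assert (part1["s1"] == part1["s3"]) and (part2["s1"] == part2["s3"])
    assert len(set(part1.values())) == len(set(part2.values())) == 3


# ---------------------------------------------------------------------------
# geographic distances


def test_haversine_one_degree_longitude():
    d = pairwise_geographic_distance(np.array([[0.0, 0.0], [0.0, 1.0]]), "degrees")
    assert d[0, 1] == pytest.approx(111_195, abs=1.0)
    assert d[0, 0] == 0.0
    assert d[1, 0] == d[0, 1]


def test_planar_distance():
    d = pairwise_geographic_distance(np.array([[0.0, 0.0], [3.0, 4.0]]), "meters")
    assert d[0, 1] == pytest.approx(5.0, abs=1e-12)


def test_missing_coordinates_rejected():
    with pytest.raises(DataFormatError):
        pairwise_geographic_distance(np.array([[0.0, np.nan]]), "meters")


def test_haplotype_dataset_invariants():
    with pytest.raises(DataFormatError):
        HaplotypeDataset(["a"], ["p"], [1], np.array([[0, 1], [2, 0]]))
    with pytest.raises(DataFormatError):
        HaplotypeDataset(["a"], ["p"], [3], np.zeros((2, 2), dtype=int))
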