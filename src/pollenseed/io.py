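"""Readers and writers: genotype CSV, GENEPOP, haplotype tables, aligned FASTA.

The canonical genotype CSV has header ``id,pop,subpop,lat,lon,
<locus>_1,<locus>_2,...`` (``x``/``y`` instead of ``lat``/``lon`` for
planar coordinates in meters).  Missing genotypes are empty fields or
``NA``.  The GENEPOP dialect follows the classic layout (title line,
locus names, ``POP`` blocks) with 2- or 3-digit allele encoding
auto-detected from token width and ``00``/``000`` marking a missing
copy; coordinates are not representable in GENEPOP and are dropped.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .datasets import MISSING, DataFormatError, GenotypeDataset, HaplotypeDataset

EARTH_RADIUS_M = 6_371_000.0

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "read_genotype_csv",
    "write_genotype_csv",
    "read_genepop",
    "write_genepop",
    "read_haplotype_csv",
    "write_haplotype_csv",
    "collapse_fasta_to_haplotypes",
    "pairwise_geographic_distance",
]


# ---------------------------------------------------------------------------
# genotype tables


def read_genotype_table(path: str | Path, dialect: str = "csv") -> GenotypeDataset:
    """Read a genotype table in the ``csv`` or ``genepop`` dialect."""
    if dialect == "csv":
        return read_genotype_csv(path)
    if dialect == "genepop":
        return read_genepop(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_genotype_table(
    dataset: GenotypeDataset, path: str | Path, dialect: str = "csv"
) -> None:
    if dialect == "csv":
        write_genotype_csv(dataset, path)
    elif dialect == "genepop":
        write_genepop(dataset, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _parse_allele(token, path, row) -> int:
    if pd.isna(token) or str(token).strip() in ("", "NA", "nan"):
        return MISSING
    try:
        value = int(float(token))
    except (TypeError, ValueError):
        raise DataFormatError(
            f"{path}: unparseable allele token {token!r} in row {row}"
        ) from None
    if value < 0:
        raise DataFormatError(f"{path}: negative allele {token!r} in row {row}")
    return value


def read_genotype_csv(path: str | Path) -> GenotypeDataset:
    df = pd.read_csv(path, dtype=str)
    cols = list(df.columns)
    meta = [c for c in cols if c in ("id", "pop", "subpop", "lat", "lon", "x", "y")]
    if "id" not in meta or "pop" not in meta:
        raise DataFormatError(f"{path}: header must contain 'id' and 'pop'")
    allele_cols = [c for c in cols if c not in meta]
    if len(allele_cols) % 2 != 0:
        raise DataFormatError(f"{path}: odd number of allele columns")
    loci: list[str] = []
    for i in range(0, len(allele_cols), 2):
        c1, c2 = allele_cols[i], allele_cols[i + 1]
        if not (c1.endswith("_1") and c2.endswith("_2") and c1[:-2] == c2[:-2]):
            raise DataFormatError(
                f"{path}: allele columns must come in <locus>_1,<locus>_2 "
                f"pairs, got {c1!r},{c2!r}"
            )
        loci.append(c1[:-2])

    n = len(df)
    genotypes = np.zeros((n, len(loci), 2), dtype=np.int64)
    for l, locus in enumerate(loci):
        for k in (1, 2):
            col = df[f"{locus}_{k}"]
            genotypes[:, l, k - 1] = [
                _parse_allele(v, path, i + 2) for i, v in enumerate(col)
            ]

    subpop = None
    if "subpop" in df.columns and df["subpop"].notna().any():
        subpop = ["" if pd.isna(s) else str(s) for s in df["subpop"]]

    coords = None
    units = None
    for pair, u in ((("lat", "lon"), "degrees"), (("x", "y"), "meters")):
        if pair[0] in df.columns and pair[1] in df.columns:
            a = pd.to_numeric(df[pair[0]], errors="coerce")
            b = pd.to_numeric(df[pair[1]], errors="coerce")
            if a.notna().any() or b.notna().any():
                coords = np.column_stack([a.to_numpy(float), b.to_numpy(float)])
                units = u
            break

    return GenotypeDataset(
        individual_id=[str(i) for i in df["id"]],
        population=[str(p) for p in df["pop"]],
        loci=loci,
        genotypes=genotypes,
        subpopulation=subpop,
        coords=coords,
        coord_units=units,
    )


def write_genotype_csv(dataset: GenotypeDataset, path: str | Path) -> None:
    data: dict[str, list] = {
        "id": dataset.individual_id,
        "pop": dataset.population,
    }
    if dataset.subpopulation is not None:
        data["subpop"] = dataset.subpopulation
    if dataset.coords is not None:
        names = ("lat", "lon") if dataset.coord_units == "degrees" else ("x", "y")
        data[names[0]] = dataset.coords[:, 0]
        data[names[1]] = dataset.coords[:, 1]
    for l, locus in enumerate(dataset.loci):
        for k in (0, 1):
            col = dataset.genotypes[:, l, k]
            data[f"{locus}_{k + 1}"] = ["" if a == MISSING else int(a) for a in col]
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GENEPOP


def read_genepop(path: str | Path) -> GenotypeDataset:
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise DataFormatError(f"{path}: truncated GENEPOP file")
    body = lines[1:]

    # locus names: either one per line or comma-separated on one line,
    # up to the first POP marker
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().upper() != "POP":
        chunk = body[i].strip()
        if chunk:
            loci.extend(s.strip() for s in chunk.split(",") if s.strip())
        i += 1
    if i == len(body):
        raise DataFormatError(f"{path}: no POP block found")

    ids: list[str] = []
    pops: list[str] = []
    rows: list[list[int]] = []
    pop_index = 0
    for lineno, raw in enumerate(body[i:], start=i + 2):
        line = raw.strip()
        if not line:
            continue
        if line.upper() == "POP":
            pop_index += 1
            continue
        if "," not in line:
            raise DataFormatError(f"{path}: line {lineno}: missing ',' separator")
        name, _, geno = line.partition(",")
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise DataFormatError(
                f"{path}: line {lineno}: expected {len(loci)} genotype tokens, "
                f"got {len(tokens)}"
            )
        alleles: list[int] = []
        for tok in tokens:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise DataFormatError(
                    f"{path}: line {lineno}: unparseable allele token {tok!r}"
                )
            w = len(tok) // 2
            alleles.extend((int(tok[:w]), int(tok[w:])))
        ids.append(name.strip())
        pops.append(f"pop{pop_index}")
        rows.append(alleles)

    genotypes = np.asarray(rows, dtype=np.int64).reshape(len(ids), len(loci), 2)
    return GenotypeDataset(
        individual_id=ids, population=pops, loci=loci, genotypes=genotypes
    )


def write_genepop(
    dataset: GenotypeDataset, path: str | Path, title: str = "pollenseed export"
) -> None:
    width = 3 if dataset.genotypes.max(initial=0) > 99 else 2
    if dataset.genotypes.max(initial=0) > 999:
        raise DataFormatError("GENEPOP cannot encode alleles above 999")
    out = [title]
    out.extend(dataset.loci)
    groups = np.asarray(dataset.population)
    for pop in dataset.populations:
        out.append("POP")
        for i in np.flatnonzero(groups == pop):
            tokens = [
                f"{a:0{width}d}{b:0{width}d}" for a, b in dataset.genotypes[i]
            ]
            out.append(f"{dataset.individual_id[i]} , " + " ".join(tokens))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# haplotypes


def read_haplotype_csv(
    path: str | Path, distance_matrix: np.ndarray | None = None
) -> HaplotypeDataset:
    """Read an ``id,pop,haplotype`` table.

    Without an explicit ``distance_matrix`` every pair of distinct
    haplotypes is placed one mutational step apart (identity distances).
    """
    df = pd.read_csv(path, dtype={"id": str, "pop": str, "haplotype": int})
    for col in ("id", "pop", "haplotype"):
        if col not in df.columns:
            raise DataFormatError(f"{path}: missing column {col!r}")
    hap = df["haplotype"].to_numpy()
    if distance_matrix is None:
        k = int(hap.max(initial=1))
        distance_matrix = np.ones((k, k), dtype=np.int64) - np.eye(k, dtype=np.int64)
    return HaplotypeDataset(
        individual_id=list(df["id"]),
        population=list(df["pop"]),
        haplotype_id=hap,
        distance_matrix=distance_matrix,
    )


def write_haplotype_csv(dataset: HaplotypeDataset, path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": dataset.individual_id,
            "pop": dataset.population,
            "haplotype": dataset.haplotype_id,
        }
    ).to_csv(path, index=False)


def collapse_fasta_to_haplotypes(
    fasta_path: str | Path,
    population_map: dict[str, str] | str | Path,
    ambiguity_policy: str = "drop_columns",
) -> HaplotypeDataset:
    """Collapse an aligned FASTA into haplotypes.

    Columns containing any gap or non-ACGT symbol in *any* sequence are
    removed globally (complete-column deletion), so the resulting
    haplotype distances form a true Hamming metric on the retained
    columns.  Identical retained strings share one haplotype id,
    numbered by first occurrence.
    """
    if ambiguity_policy != "drop_columns":
        raise ValueError(f"unknown ambiguity policy {ambiguity_policy!r}")
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise DataFormatError(f"{fasta_path}: empty FASTA")
    if not isinstance(population_map, dict):
        mp = pd.read_csv(population_map, dtype=str)
        population_map = dict(zip(mp["id"], mp["pop"]))

    seqs = [str(r.seq).upper() for r in records]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise DataFormatError("sequences are not aligned (unequal lengths)")

    arr = np.array([list(s) for s in seqs])
    keep = np.all(np.isin(arr, list("ACGT")), axis=0)
    if not keep.any():
        raise DataFormatError("no unambiguous columns remain after filtering")
    arr = arr[:, keep]

    hap_of: dict[str, int] = {}
    ids = np.empty(len(records), dtype=np.int64)
    rep: list[np.ndarray] = []
    for i, row in enumerate(arr):
        key = "".join(row)
        if key not in hap_of:
            hap_of[key] = len(hap_of) + 1
            rep.append(row)
        ids[i] = hap_of[key]

    k = len(rep)
    dist = np.zeros((k, k), dtype=np.int64)
    for a in range(k):
        for b in range(a + 1, k):
            d = int((rep[a] != rep[b]).sum())
            dist[a, b] = dist[b, a] = d

    names = [r.id for r in records]
    missing = [n for n in names if n not in population_map]
    if missing:
        raise DataFormatError(f"no population label for sequences {missing}")
    return HaplotypeDataset(
        individual_id=names,
        population=[population_map[n] for n in names],
        haplotype_id=ids,
        distance_matrix=dist,
    )


# ---------------------------------------------------------------------------
# geography


def pairwise_geographic_distance(
    coords: np.ndarray, units: str = "degrees"
) -> np.ndarray:
    """Pairwise distances in meters between individuals.

    ``degrees`` coordinates (lat, lon) are put through the haversine
    great-circle formula on a sphere of radius 6,371,000 m; ``meters``
    coordinates are planar Euclidean.
    """
    coords = np.asarray(coords, dtype=float)
    if np.isnan(coords).any():
        raise DataFormatError("missing coordinates for an included individual")
    if units == "meters":
        diff = coords[:, None, :] - coords[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))
    if units != "degrees":
        raise ValueError(f"unknown coordinate units {units!r}")
    lat = np.radians(coords[:, 0])
    lon = np.radians(coords[:, 1])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    )
    a = np.clip(a, 0.0, 1.0)
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))
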