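"""Full-analysis driver: runs every estimation stage on one dataset pair
and writes one TSV/JSON per result table plus a combined JSON bundle.

Every output JSON embeds provenance metadata: package version, a hash
of the configuration, the RNG seed, and SHA-256 checksums of the input
files, so a bundle can always be traced back to its exact inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .amova import Amova
from .datasets import GenotypeDataset, HaplotypeDataset
from .fstats import PairwiseFst, WeirCockerhamFst, null_allele_table, summary_diversity
from .geneflow import PollenSeedGeneFlow, haplotype_diversity
from .io import pairwise_geographic_distance, read_genotype_table, read_haplotype_csv
from .sgs import KinshipDistanceRegression, loiselle_kinship

log = logging.getLogger("pollenseed")

__all__ = ["AnalysisConfig", "run_full_analysis"]


@dataclass
class AnalysisConfig:
    """Settings for the end-to-end analysis.

    Defaults follow the field conventions this pipeline reproduces:
    10,000 permutations for every permutation test and a 10 km ceiling
    on the kinship-distance regression.
    """

    genotypes: str
    haplotypes: str | None = None
    dialect: str = "csv"
    by: str = "population"
    n_perm: int = 10_000
    max_distance: float = 10_000.0
    seed: int = 42
    out_dir: str = "pollenseed_out"
    sgs: bool = True
    rounding: dict = field(
        default_factory=lambda: {"fstats": 4, "t": 4, "r": 2, "sp": 3}
    )


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _metadata(config: AnalysisConfig) -> dict:
    cfg = asdict(config)
    meta = {
        "package": "pollenseed",
        "version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:16],
        "inputs": {},
    }
    for key in ("genotypes", "haplotypes"):
        p = cfg.get(key)
        if p and Path(p).exists():
            meta["inputs"][key] = {"path": str(p), "sha256": _checksum(p)}
    return meta


def _dump(obj: dict, path: Path, meta: dict) -> None:
    payload = {"metadata": meta, **obj}
    path.write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        v = float(x)
        return None if np.isnan(v) else v
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run diversity -> F-statistics -> pairwise F_ST -> AMOVA (both
    genomes) -> SGS per population -> pollen/seed gene flow.

    Returns the combined report dictionary; one TSV/JSON per stage is
    written under ``config.out_dir``.  Any stage failure aborts with a
    stage-labelled error; outputs of completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = _metadata(config)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    stage_seed = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]
    report: dict = {"metadata": meta}

    def stage(name):
        log.info("stage %s", name)
        return name

    try:
        name = stage("read_inputs")
        genotypes: GenotypeDataset = read_genotype_table(
            config.genotypes, config.dialect
        )
        log.info(
            "read %d individuals, %d loci, %d populations",
            genotypes.n_individuals,
            genotypes.n_loci,
            len(genotypes.populations),
        )
        haplotypes: HaplotypeDataset | None = None
        if config.haplotypes:
            haplotypes = read_haplotype_csv(config.haplotypes)
            log.info(
                "read %d haplotyped individuals (%d haplotypes)",
                haplotypes.n_individuals,
                haplotypes.n_haplotypes,
            )

        name = stage("summary_diversity")
        div = summary_diversity(genotypes, config.by)
        div.to_csv(out / "diversity.tsv", sep="\t")
        nulls = null_allele_table(genotypes, config.by)
        nulls.to_csv(out / "null_alleles.tsv", sep="\t")
        report["diversity"] = div.reset_index().to_dict(orient="list")

        name = stage("wc_f_statistics")
        fres = WeirCockerhamFst(genotypes, config.by).fit()
        fres.per_locus.to_csv(out / "fstats_per_locus.tsv", sep="\t")
        _dump(fres.to_dict(), out / "fstats.json", meta)
        report["fstats"] = fres.to_dict()

        name = stage("pairwise_fst")
        if len(genotypes.populations) >= 2:
            pw = PairwiseFst(genotypes, config.by).fit(
                n_perm=config.n_perm, seed=stage_seed[0]
            )
            pw.fst.to_csv(out / "pairwise_fst.tsv", sep="\t")
            pw.p_value.to_csv(out / "pairwise_fst_p.tsv", sep="\t")
            report["pairwise_fst"] = pw.fst.to_dict()

        name = stage("amova_nuclear")
        am_nuc = Amova.from_genotypes(genotypes, config.by).fit(
            n_perm=config.n_perm, seed=stage_seed[1]
        )
        _dump(am_nuc.to_dict(), out / "amova_nuclear.json", meta)
        report["amova_nuclear"] = am_nuc.to_dict()

        if haplotypes is not None:
            name = stage("amova_haplotype")
            am_hap = Amova.from_haplotypes(haplotypes).fit(
                n_perm=config.n_perm, seed=stage_seed[2]
            )
            _dump(am_hap.to_dict(), out / "amova_haplotype.json", meta)
            report["amova_haplotype"] = am_hap.to_dict()

            name = stage("haplotype_diversity")
            hd = haplotype_diversity(haplotypes)
            hd.to_csv(out / "haplotype_diversity.tsv", sep="\t")
            report["haplotype_diversity"] = hd.reset_index().to_dict(orient="list")

        if config.sgs and genotypes.coords is not None:
            name = stage("sgs")
            report["sgs"] = {}
            groups = genotypes.labels(config.by)
            dist_all = pairwise_geographic_distance(
                genotypes.coords, genotypes.coord_units
            )
            for pop in dict.fromkeys(groups):
                idx = np.flatnonzero(groups == pop)
                if len(idx) < 10:
                    log.info("skipping SGS for %s: only %d individuals", pop, len(idx))
                    continue
                sub = genotypes.subset(idx)
                try:
                    kin = loiselle_kinship(sub)
                    model = KinshipDistanceRegression(
                        kin,
                        dist_all[np.ix_(idx, idx)],
                        max_distance=config.max_distance,
                    )
                    res = model.fit(n_perm=config.n_perm, seed=stage_seed[3])
                except ValueError as exc:
                    log.info("skipping SGS for %s: %s", pop, exc)
                    continue
                res.class_table.to_csv(
                    out / f"sgs_curve_{pop}.tsv", sep="\t", index=False
                )
                _dump(res.to_dict(), out / f"sgs_{pop}.json", meta)
                report["sgs"][pop] = res.to_dict()

        if haplotypes is not None:
            name = stage("geneflow")
            gf = PollenSeedGeneFlow.from_datasets(
                genotypes, haplotypes, config.by
            ).fit()
            _dump(gf.to_dict(), out / "geneflow.json", meta)
            report["geneflow"] = gf.to_dict()
    except Exception as exc:  # noqa: BLE001 - re-raise with stage label
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    (out / "report.json").write_text(
        json.dumps(report, indent=2, default=_jsonable) + "\n"
    )
    return report
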