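"""End-to-end orchestration: ingest -> collapse -> tree -> GMYC -> classify
-> diversification diagnostics -> JSON summary.

Each stage logs its parameters and record-count changes; the single JSON
summary is the machine-readable surface downstream tooling consumes.  All
percentages are emitted together with raw fractions so no consumer depends
on a rounding convention.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import barcode_io, classify, diversify, gmyc, haplotypes, trees
from .barcode_io import BarcodeDataset, RegionRule

log = logging.getLogger("barcodiv")


@dataclass
class PipelineConfig:
    fasta: str | None = None
    metadata: str | None = None
    tree_file: str | None = None        # user-supplied ultrametric newick
    out_dir: str = "out"
    min_length: int = 401
    apply_region_filter: bool = False
    region: RegionRule = field(default_factory=RegionRule)
    min_overlap: int = 100
    tree_method: str = "upgma"          # fallback chronogram when no tree_file
    sympatry_km: float = 50.0
    divergence_floor_pct: float = 2.5
    crown_age_myr: float = 110.0
    generations_per_year: float = 1.0
    min_specimens_for_pi: int = 10
    band: tuple[float, float] = diversify.OPTIMAL_BAND
    support_floor: float = 0.01
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        region = raw.pop("region", None)
        cfg = cls(**raw)
        if region:
            cfg.region = RegionRule(**region)
        return cfg

    def echo(self, path: Path) -> None:
        data = asdict(self)
        data["band"] = list(self.band)
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def specimen_partition(haps: haplotypes.HaplotypeSet,
                       tree_partition: gmyc.EntityPartition) -> gmyc.EntityPartition:
    """Map a haplotype-level entity partition down to specimens.

    Multi-assigned records use their representative haplotype (smallest id),
    so the mapping is deterministic."""
    assignment = {
        rid: tree_partition.assignment[haps.representative_of(rid)]
        for rid in haps.membership
    }
    return gmyc.EntityPartition.from_assignment(assignment)


def run_pipeline(config: PipelineConfig,
                 dataset: BarcodeDataset | None = None) -> dict:
    """Run every stage and return (and write) the summary dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(
            level=logging.INFO,
            format="%(asctime)s %(name)s %(levelname)s %(message)s")
    fh = logging.FileHandler(out / "pipeline.log")
    fh.setFormatter(logging.Formatter(
        "%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    config.echo(out / "config.yml")
    summary: dict = {"stages": []}
    try:
        # ingest -------------------------------------------------------
        if dataset is None:
            if not config.fasta or not config.metadata:
                raise ValueError("pipeline needs fasta+metadata or a dataset")
            dataset = barcode_io.read_dataset(config.fasta, config.metadata)
        n0 = len(dataset)
        log.info("ingest: %d records, %d species", n0, len(dataset.species))
        ds = barcode_io.filter_by_length(dataset, config.min_length)
        log.info("length filter (>=%d): %d -> %d records",
                 config.min_length, n0, len(ds))
        if config.apply_region_filter:
            n_before = len(ds)
            ds = barcode_io.filter_by_region(ds, config.region)
            log.info("region filter: %d -> %d records", n_before, len(ds))
        summary["dataset"] = barcode_io.dataset_summary(ds)
        summary["stages"].append("ingest")

        # collapse -----------------------------------------------------
        haps = haplotypes.collapse_haplotypes(ds)
        log.info("collapse: %d records -> %d haplotypes", len(ds), len(haps))
        haps.to_tsv(out / "haplotypes.tsv")
        haps.to_fasta(out / "haplotypes.fasta")
        summary["n_haplotypes"] = len(haps)
        summary["stages"].append("collapse")

        # tree ---------------------------------------------------------
        if config.tree_file:
            tree = trees.parse_newick(Path(config.tree_file).read_text())
            if not trees.is_ultrametric(tree):
                raise ValueError("supplied tree is not ultrametric")
        else:
            if config.tree_method != "upgma":
                raise ValueError(
                    "no chronogram supplied and the built-in fallback is "
                    "'upgma'; set tree_method accordingly or pass tree_file")
            dm = haplotypes.build_distance_matrix(
                haps.haplotypes, min_overlap=config.min_overlap)
            tree = trees.upgma(dm)
        (out / "tree.nwk").write_text(trees.write_newick(tree) + "\n")
        summary["stages"].append("tree")

        # gmyc ---------------------------------------------------------
        fit = gmyc.fit_single_threshold(tree)
        supports = gmyc.aic_entity_supports(fit, floor=config.support_floor)
        choice = gmyc.select_st_vs_mm(fit)
        log.info("gmyc: T=%.4g, %d entities (%d clusters), logL=%.3f, p=%.3g",
                 fit.threshold, fit.partition.entity_count,
                 fit.partition.cluster_count, fit.logL, fit.lr_p_value)
        summary["gmyc"] = fit.report()
        summary["gmyc"]["model_choice"] = choice
        with open(out / "gmyc.json", "w") as jf:
            json.dump(summary["gmyc"], jf, indent=2)
        _write_entities(out / "entities.tsv", fit, supports)
        summary["stages"].append("gmyc")

        # classify -----------------------------------------------------
        part = specimen_partition(haps, fit.partition)
        species_of = ds.species_of()
        cls = classify.classify_vs_entities(species_of, part)
        classify.annotate_me_species(ds, part, cls, supports,
                                     sympatry_km=config.sympatry_km,
                                     min_overlap=config.min_overlap)
        perf = classify.assess_performance(tree, haps, species_of)
        fam = ds.family_of()
        summary["classification"] = cls.summary()
        summary["performance"] = classify.performance_summary(perf, fam)
        hd = classify.high_divergence_report(cls, config.divergence_floor_pct)
        hd.to_csv(out / "high_divergence.tsv", sep="\t", index=False)
        summary["high_divergence"] = {
            "n_species": int(len(hd)),
            "fraction_of_all_species_pct":
                hd.attrs["fraction_of_all_species_pct"],
        }
        classify.family_summary(cls, fam).to_csv(
            out / "family_summary.tsv", sep="\t", index=False)
        summary["stages"].append("classify")

        # diversification diagnostics ---------------------------------
        ne_estimates = []
        per_species: dict[str, list[str]] = {}
        for rec in ds.records:
            per_species.setdefault(rec.species, []).append(rec.sequence)
        for sp, seqs in sorted(per_species.items()):
            if len(seqs) < config.min_specimens_for_pi:
                continue
            try:
                pi = diversify.synonymous_pi(
                    seqs, min_sequences=config.min_specimens_for_pi)
            except ValueError as exc:
                log.warning("pi skipped for %s: %s", sp, exc)
                continue
            ne_estimates.append(diversify.NeEstimate.from_pi(
                sp, len(seqs), pi, config.generations_per_year))
        sr_species = diversify.yule_crown_rate(
            len(per_species), config.crown_age_myr)
        sr_entities = diversify.yule_crown_rate(
            max(cls.entity_count, 2), config.crown_age_myr)
        summary["diversification"] = {
            "speciation_rate_species": sr_species,
            "speciation_rate_entities": sr_entities,
            "n_ne_estimates": len(ne_estimates),
        }
        if ne_estimates:
            ne_values = [e.ne_slow for e in ne_estimates] + \
                        [e.ne_fast for e in ne_estimates]
            report = diversify.suitability_check(ne_values, sr_species,
                                                 band=config.band)
            summary["diversification"]["suitability"] = report.summary()
            _write_ne_table(out / "ne_estimates.tsv", ne_estimates)
        summary["stages"].append("divstats")

        summary["seed"] = config.seed
        with open(out / "summary.json", "w") as jf:
            json.dump(summary, jf, indent=2, default=float)
        return summary
    except Exception as exc:
        stage = summary["stages"][-1] if summary["stages"] else "ingest"
        log.error("pipeline failed after stage %r: %s", stage, exc)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()


def _write_entities(path: Path, fit: gmyc.GmycFit,
                    supports: gmyc.NodeSupport) -> None:
    with open(path, "w") as fh:
        fh.write("tip\tentity_id\tst_support\tmm_support\n")
        for tip in sorted(fit.partition.assignment):
            eid = fit.partition.assignment[tip]
            tips = fit.partition.entities[eid]
            st = supports.st_supports.get(tips, 0.0)
            mm = supports.mm_supports.get(tips, st)
            fh.write(f"{tip}\t{eid}\t{st:.4f}\t{mm:.4f}\n")


def _write_ne_table(path: Path, estimates) -> None:
    with open(path, "w") as fh:
        fh.write("species\tn_specimens\tpi_syn\tne_slow\tne_fast\n")
        for e in estimates:
            fh.write(f"{e.species}\t{e.n_specimens}\t{e.pi_syn:.6g}\t"
                     f"{e.ne_slow:.6g}\t{e.ne_fast:.6g}\n")
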