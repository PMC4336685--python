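"""End-to-end orchestration: simulate -> demux -> stacks -> catalog ->
genotype -> screen -> summarize, as one reproducible, seeded run.

All randomness flows from the single config seed through named substreams,
one per stochastic stage, so re-running an identical config is byte-identical
in every output file.  Each stage logs its input/output row counts; any stage
failure aborts with the stage name attached.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import demux as demux_mod
from . import evaluate as eval_mod
from .genotype import MISSING, call_genotypes, is_het, write_genotype_matrix
from .samples import FEMALE, Individual, sexes_of, write_sample_sheet
from .screen import (
    SexSystemCall,
    candidates_to_frame,
    chance_cosegregation_probability,
    filter_parent_polymorphic,
    infer_sex_system,
    screen_sex_association,
)
from .simulate import (
    CrossResult,
    ReadSimParams,
    SimGenome,
    generate_mids,
    plant_variants,
    simulate_cross,
    simulate_genome,
    simulate_reads,
    write_truth_table,
)
from .stacks import build_catalog, build_stacks_for
from .summary import SummaryRow, summarize_group, summarize_individual

logger = logging.getLogger("radsex")

_STAGE_STREAMS = ("genome", "variants", "cross", "mids", "reads")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and its context."""


@dataclass
class RunConfig:
    """All stage parameters of one run.

    Defaults are the standard demonstration cross: a 100-kb genome carrying
    150 planted EcoRI sites with a 20% sex-determining region, 5 sex-linked
    plus 200 autosomal SNPs, 8 female + 8 male F1 progeny and the two
    parents, 20x mean tag depth and 0.5% sequencing error.
    """

    seed: int = 17
    outdir: str = "radsex_run"
    # genome
    genome_length: int = 100_000
    n_ecoRI_target: int = 150
    sex_region_fraction: float = 0.2
    # variants
    n_sex_linked: int = 5
    n_autosomal: int = 200
    # cross
    n_female: int = 8
    n_male: int = 8
    sex_system: str = "ZW"
    balanced: bool = True
    # reads
    mean_depth_per_tag: float = 20.0
    error_rate: float = 0.005
    # demux
    barcode_mismatch: int = 0
    # stacks/catalog
    min_stack_depth: int = 3
    catalog_mismatch: int = 2
    # genotyping
    min_allele_depth: int = 2
    min_minor_ratio: float = 0.1
    # screen
    max_missing: int = 0
    marker_prefix: str = "SIM"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(len(_STAGE_STREAMS))
        return {
            name: int(s) % 2**31 for name, s in zip(_STAGE_STREAMS, state)
        }


@dataclass
class PipelineResult:
    config: RunConfig
    outdir: Path
    genome: SimGenome
    cross: CrossResult
    manifest: dict
    demux: demux_mod.DemuxResult
    stacks_by_individual: dict
    catalog: list
    matrix: pd.DataFrame
    reduced: pd.DataFrame
    filter_stats: dict
    candidates: list
    system: SexSystemCall
    summary_table: pd.DataFrame
    evaluation: dict = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def _per_individual_summaries(
    result_counts: pd.Series,
    stacks_by_individual: dict,
    demux_reads: dict[str, list[str]],
    matrix: pd.DataFrame,
    catalog: list,
    individuals: list[Individual],
    genome_size: int,
) -> tuple[list[SummaryRow], list[str]]:
    ref_base = {}
    for locus in catalog:
        for pos in locus.variant_positions:
            ref_base[(locus.locus_id, pos)] = locus.reference_consensus[pos - 1]
    rows, groups = [], []
    for ind in individuals:
        iid = ind.individual_id
        seqs = demux_reads.get(iid, [])
        gc = sum(s.count("G") + s.count("C") for s in seqs)
        bases = sum(len(s) for s in seqs)
        total_snp = het_snp = 0
        if len(matrix):
            col = matrix[iid]
            for key, call in col.items():
                if call == MISSING:
                    continue
                ref = ref_base.get(key)
                if is_het(call):
                    total_snp += 1
                    het_snp += 1
                elif ref is not None and call != f"{ref}/{ref}":
                    total_snp += 1
        rows.append(
            summarize_individual(
                iid,
                read_number=int(result_counts[iid]),
                n_rad_tags=len(stacks_by_individual.get(iid, [])),
                genome_size=genome_size,
                gc_count=gc,
                base_count=bases,
                total_snp=total_snp,
                het_snp_rate=(
                    round(100 * het_snp / total_snp, 1) if total_snp else None
                ),
            )
        )
        groups.append(ind.sex)
    return rows, groups


def run_pipeline(config: RunConfig, evaluate: bool = True) -> PipelineResult:
    """Execute every stage into ``config.outdir`` and return all artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "pipeline.log")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)
    seeds = config.stage_seeds()

    try:
        genome = _stage("simulate_genome")(simulate_genome)(
            config.genome_length,
            config.n_ecoRI_target,
            config.sex_region_fraction,
            seed=seeds["genome"],
        )
        logger.info(
            "genome: %d nt, %d EcoRI sites (%d usable), sex region %s",
            genome.length, len(genome.ecoRI_sites), len(genome.usable_sites),
            genome.sex_region,
        )

        variants = _stage("plant_variants")(plant_variants)(
            genome, config.n_sex_linked, config.n_autosomal, seed=seeds["variants"]
        )
        cross = _stage("simulate_cross")(simulate_cross)(
            genome, variants, config.n_female, config.n_male,
            seed=seeds["cross"], sex_system=config.sex_system,
            balanced=config.balanced,
        )
        individuals = cross.pedigree.individuals
        mids = dict(
            zip(
                [i.individual_id for i in individuals],
                generate_mids(len(individuals), seed=seeds["mids"]),
            )
        )
        sheet = [
            Individual(i.individual_id, i.sex, i.role, mids[i.individual_id])
            for i in individuals
        ]
        write_sample_sheet(sheet, outdir / "samples.tsv")
        write_truth_table(cross.truth, outdir / "truth.tsv")

        params = ReadSimParams(
            mean_depth_per_tag=config.mean_depth_per_tag,
            error_rate=config.error_rate,
            seed=seeds["reads"],
        )
        fastq = outdir / "reads.fastq"
        manifest = _stage("simulate_reads")(simulate_reads)(
            genome, cross, params, mids, fastq
        )
        logger.info("reads: %d total over %d individuals",
                    manifest["total_reads"], len(individuals))

        dm = _stage("demux")(demux_mod.demultiplex)(
            fastq, sheet, barcode_mismatch=config.barcode_mismatch
        )
        if dm.total == 0:
            raise PipelineError(
                "stage 'demux' failed: input FASTQ contains zero reads"
            )
        demux_mod.write_demuxed(dm, outdir / "demux")
        logger.info("demux: %d/%d assigned, discards=%s",
                    dm.assigned, dm.total, dict(dm.discards))

        stacks_by_individual = {}
        stack_rows = []
        for ind in individuals:
            iid = ind.individual_id
            stx, _residual = _stage("build_stacks")(build_stacks_for)(
                iid, dm.reads[iid], min_stack_depth=config.min_stack_depth
            )
            stacks_by_individual[iid] = stx
            stack_rows += [(iid, s.consensus, s.depth, s.members) for s in stx]
        pd.DataFrame(
            stack_rows, columns=["individual_id", "consensus", "depth", "members"]
        ).to_csv(outdir / "stacks.tsv", sep="\t", index=False)
        logger.info("stacks: %d total", len(stack_rows))

        catalog = _stage("build_catalog")(build_catalog)(
            stacks_by_individual,
            catalog_mismatch=config.catalog_mismatch,
            parent_ids=("mother", "father"),
            min_variant_depth=config.min_allele_depth,
            min_variant_ratio=config.min_minor_ratio,
        )
        pd.DataFrame(
            [
                (
                    l.locus_id,
                    l.reference_consensus,
                    ",".join(map(str, l.variant_positions)),
                    l.repetitive,
                    len(l.alleles),
                )
                for l in catalog
            ],
            columns=[
                "locus_id", "reference_consensus", "variant_positions",
                "repetitive", "n_individuals",
            ],
        ).to_csv(outdir / "catalog.tsv", sep="\t", index=False)
        logger.info("catalog: %d loci (%d repetitive)",
                    len(catalog), sum(l.repetitive for l in catalog))

        ind_ids = [i.individual_id for i in individuals]
        matrix, notes = _stage("genotype")(call_genotypes)(
            catalog, ind_ids,
            min_allele_depth=config.min_allele_depth,
            min_minor_ratio=config.min_minor_ratio,
        )
        write_genotype_matrix(matrix, outdir / "genotypes.tsv")
        notes.to_csv(outdir / "genotype_notes.tsv", sep="\t", index=False)
        logger.info("genotypes: %d variant rows", len(matrix))

        reduced, fstats = _stage("parent_filter")(filter_parent_polymorphic)(
            matrix, "mother", "father"
        )
        logger.info("parent filter: %s", fstats)

        candidates = _stage("screen")(screen_sex_association)(
            reduced, sexes_of(individuals), max_missing=config.max_missing,
            catalog=catalog, name_prefix=config.marker_prefix,
        )
        system = infer_sex_system(candidates)
        candidates_to_frame(candidates).to_csv(
            outdir / "candidates.tsv", sep="\t", index=False
        )
        logger.info("screen: %d candidates, system=%s", len(candidates), system.system)

        rows, groups = _per_individual_summaries(
            dm.counts, stacks_by_individual, dm.reads, matrix, catalog,
            individuals, genome.length,
        )
        summary_table = summarize_group(rows, groups)
        summary_table.to_csv(outdir / "summary.tsv", sep="\t", index=False)

        evaluation: dict = {}
        if evaluate:
            site_map = eval_mod.map_loci_to_sites(catalog, genome)
            conc = eval_mod.genotype_concordance(
                matrix, cross.truth, site_map, ind_ids
            )
            expected_het_sex = FEMALE if config.sex_system == "ZW" else "male"
            frac, n_rec, n_planted = eval_mod.sex_marker_recovery(
                candidates, cross.truth, site_map, expected_het_sex
            )
            evaluation = {
                "genotype_concordance": conc.concordance,
                "concordance_cells": conc.n_cells,
                "concordance_mismatch": conc.n_mismatch,
                "concordance_missing": conc.n_missing,
                "concordance_absent_rows": conc.n_absent_rows,
                "sex_marker_recovery": frac,
                "sex_markers_recovered": n_rec,
                "sex_markers_planted": n_planted,
            }
            logger.info("evaluation: %s", evaluation)

        report = {
            "sex_system": asdict(system),
            "n_candidates": len(candidates),
            "chance_cosegregation_probability": chance_cosegregation_probability(
                config.n_female, config.n_male
            ),
            "parent_filter": fstats,
            "evaluation": evaluation,
        }
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        full_manifest = {
            "config": asdict(config),
            "stage_seeds": seeds,
            "reads": manifest,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(full_manifest, fh, indent=2)

        return PipelineResult(
            config=config,
            outdir=outdir,
            genome=genome,
            cross=cross,
            manifest=full_manifest,
            demux=dm,
            stacks_by_individual=stacks_by_individual,
            catalog=catalog,
            matrix=matrix,
            reduced=reduced,
            filter_stats=fstats,
            candidates=candidates,
            system=system,
            summary_table=summary_table,
            evaluation=evaluation,
        )
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()
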