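"""End-to-end pipeline: (simulate) -> diversity -> Fst -> sweep scan ->
population-specific SNPs -> annotation -> report.

Outputs are plain TSV/JSON files in the output directory; identical config
and seed give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import diversity, fst, specific, sweep
from .io import (
    GenotypeMatrix, PopulationMap, genotype_matrix_from_variants,
    read_fasta, read_gff, read_popmap, read_vcf, write_fasta, write_gff,
    write_popmap, write_tsv, write_vcf,
)
from .simulate import demo_scene

logger = logging.getLogger("selsweep")


@dataclass
class PipelineConfig:
    vcf: str | None = None          # None -> simulate the demo scene
    popmap: str | None = None
    gff: str | None = None
    fasta: str | None = None
    outdir: str = "selsweep_out"
    focal_pop: str = "popC"
    window_size: int = 20_000
    step: int = 5_000
    fst_tail: float = 0.01
    ratio_tail: float = 0.01
    ratio_mode: str = "top"
    specific_threshold: float = 0.8
    region_size: int = 1_000_000
    alpha: float = 0.005
    fst_threshold: float = 0.15
    max_missing: float = 1.0
    chromosomes: list[str] | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)


@dataclass
class RunReport:
    config: dict
    n_samples: int = 0
    n_snp_sites: int = 0
    n_indels: int = 0
    populations: list[str] = field(default_factory=list)
    population_summary: list[dict] = field(default_factory=list)
    fst_extremes: dict = field(default_factory=dict)
    n_windows: int = 0
    n_outlier_windows: int = 0
    n_selected_regions: int = 0
    selected_region_genes: list[str] = field(default_factory=list)
    n_specific_calls_focal: int = 0
    n_specific_calls_other: int = 0
    n_significant_bins: int = 0
    annotation_counts: dict = field(default_factory=dict)
    transition_fraction: float = float("nan")
    version: str = ""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.time()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                logger.error("stage %s: FAILED (%s)", name, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed") from exc
            logger.info("stage %s: done in %.2fs", name, time.time() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> RunReport:
    from . import __version__

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config), version=__version__)

    # ---- inputs (simulated when no VCF given) ----
    if config.vcf is None:
        scene = demo_scene(config.seed)
        matrix, popmap, genome = (
            scene["matrix"], scene["popmap"], scene["genome"]
        )
        chrom_lengths = dict(scene["config"].chrom_lengths)
        gene_models = genome.genes
        seqs = genome.sequences
        write_vcf(matrix, outdir / "simulated.vcf", chrom_lengths)
        write_popmap(popmap, outdir / "simulated.popmap.tsv")
        write_fasta(seqs, outdir / "simulated.fa")
        write_gff(gene_models, outdir / "simulated.gff3")
        variants, _ = read_vcf(outdir / "simulated.vcf")
        logger.info("simulated %d sites x %d samples",
                    matrix.n_sites, matrix.n_samples)
    else:
        variants, samples = read_vcf(config.vcf)
        matrix = genotype_matrix_from_variants(variants, samples)
        if config.popmap is None:
            raise ValueError("a popmap is required with an input VCF")
        popmap = read_popmap(config.popmap)
        popmap.validate_against(matrix.samples)
        gene_models = read_gff(config.gff) if config.gff else []
        seqs = read_fasta(config.fasta) if config.fasta else None
        chrom_lengths = matrix.chrom_lengths()
        if seqs:
            for c, s in seqs.items():
                chrom_lengths[c] = len(s)

    if config.chromosomes:
        keep = np.isin(matrix.chrom, config.chromosomes)
        matrix = matrix.subset_sites(keep)
        chrom_lengths = {
            c: L for c, L in chrom_lengths.items() if c in config.chromosomes
        }
    matrix = matrix.filter_missingness(config.max_missing)
    indels = [v for v in variants if v.is_indel]
    report.n_samples = matrix.n_samples
    report.n_snp_sites = matrix.n_sites
    report.n_indels = len(indels)
    report.populations = list(popmap.populations)
    scheme = diversity.WindowScheme(config.window_size, config.step)
    groups = popmap.group_indices(matrix.samples)

    # ---- per-population diversity ----
    summary = _stage("population_summary")(diversity.population_summary)(
        matrix, popmap
    )
    write_tsv(summary, outdir / "population_summary.tsv")
    report.population_summary = summary.to_dict("records")

    pi = _stage("windowed_pi")(diversity.windowed_pi)(
        matrix, groups, scheme, chrom_lengths
    )
    write_tsv(pi, outdir / "windowed_pi.tsv")
    taj = _stage("windowed_tajima")(diversity.windowed_tajimas_d)(
        matrix, groups, scheme, chrom_lengths
    )
    write_tsv(taj, outdir / "windowed_tajima_d.tsv")

    # ---- pairwise Fst ----
    fst_mat = _stage("pairwise_fst")(fst.genomewide_pairwise_fst)(
        matrix, popmap
    )
    fst.write_fst_matrix(fst_mat, outdir / "fst_matrix.tsv")
    ext = fst.fst_extremes(fst_mat, config.fst_threshold)
    report.fst_extremes = {
        "min_pair": list(ext["min_pair"]), "min_value": ext["min_value"],
        "max_pair": list(ext["max_pair"]), "max_value": ext["max_value"],
        "n_above_threshold": len(ext["above_threshold"]),
        "threshold": ext["threshold"],
    }

    # ---- sweep scan: focal vs pooled others ----
    focal_idx = popmap.indices(config.focal_pop, matrix.samples)
    if len(focal_idx) == 0:
        raise ValueError(f"focal population {config.focal_pop!r} not found")
    other_idx = np.setdiff1d(np.arange(matrix.n_samples), focal_idx)
    stats = _stage("window_stats")(sweep.compute_window_stats)(
        matrix, focal_idx, other_idx, scheme, chrom_lengths
    )
    write_tsv(stats, outdir / "window_stats.tsv")
    cfg = sweep.OutlierConfig(config.fst_tail, config.ratio_tail,
                              config.ratio_mode)
    outliers = _stage("select_outliers")(sweep.select_outliers)(stats, cfg)
    regions = sweep.merge_regions(outliers)
    regions = sweep.annotate_regions(regions, gene_models)
    write_tsv(sweep.regions_to_tsv_1based(regions),
              outdir / "selected_regions.tsv")
    report.n_windows = len(stats)
    report.n_outlier_windows = len(outliers)
    report.n_selected_regions = len(regions)
    report.selected_region_genes = sorted({
        g for cell in regions.genes for g in cell.split(",") if g
    })

    # ---- population-specific SNPs: focal vs pooled others ----
    calls_f = _stage("specific_calls")(specific.call_population_specific)(
        matrix, focal_idx, other_idx, config.specific_threshold
    )
    calls_o = specific.call_population_specific(
        matrix, other_idx, focal_idx, config.specific_threshold
    )
    write_tsv(calls_f, outdir / "specific_snps_focal.tsv")
    write_tsv(calls_o, outdir / "specific_snps_other.tsv")
    counts_f = specific.count_per_region(calls_f, chrom_lengths,
                                         config.region_size)
    counts_o = specific.count_per_region(calls_o, chrom_lengths,
                                         config.region_size)
    comp = specific.compare_region_counts(
        counts_f, counts_o, len(calls_f), len(calls_o), config.alpha
    )
    write_tsv(comp, outdir / "specific_snp_bins.tsv")
    shared = specific.shared_specific_summary(
        {"focal": calls_f, "other": calls_o}
    )
    write_tsv(shared, outdir / "specific_snps_shared.tsv")
    if gene_models:
        genes = specific.genes_per_group(
            {"focal": calls_f, "other": calls_o}, gene_models
        )
        write_tsv(genes, outdir / "specific_snp_genes.tsv")
    report.n_specific_calls_focal = len(calls_f)
    report.n_specific_calls_other = len(calls_o)
    report.n_significant_bins = int(comp.significant.sum())

    # ---- functional annotation ----
    if gene_models:
        annotations = _stage("annotation")(ann.annotate_variants)(
            [v for v in variants if v.is_snp and v.is_biallelic],
            gene_models, seqs,
        )
        summ = ann.summarize_annotations(annotations)
        write_tsv(summ, outdir / "annotation_summary.tsv")
        report.annotation_counts = dict(zip(summ.category, summ["count"]))
    spectrum = ann.mutation_spectrum(variants)
    write_tsv(spectrum, outdir / "mutation_spectrum.tsv")
    total = spectrum.total.sum()
    if total > 0:
        ts = spectrum.set_index("class").total
        report.transition_fraction = float(
            sum(ts[c] for c in ann.TRANSITION_CLASSES) / total
        )
    lengths_df = ann.indel_lengths(variants)
    write_tsv(lengths_df, outdir / "indel_lengths.tsv")

    with open(outdir / "report.json", "w") as fh:
        json.dump(asdict(report), fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", outdir)
    return report
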