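"""End-to-end orchestration: one YAML config drives simulation, SE calling,
the SE-gene screen, single-nucleus DE, the gene-set intersection, bait
interaction profiling and the cohort/variant arithmetic, producing a manifest
of every artifact with parameter snapshots and checksums."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io, se_calling, se_genes, sc_de, htgts3c, cohort_variants
from .errors import ConfigurationError, SeloopkitError
from .synthetic_data import (
    SimulationConfig,
    bait_spec_for,
    generate_genome,
    simulate_3c_reads,
    simulate_chip_inputs,
    simulate_cohort_and_variants,
    simulate_counts,
    simulate_expression,
    simulate_screen_gene_lists,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("sim", "se_calling", "se_genes", "sc_de", "intersect", "htgts3c", "cohort")


@dataclass
class PipelineConfig:
    outdir: str = "seloopkit_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # thresholds (the study's stated cutoffs are the defaults)
    stitch_distance: int = se_calling.DEFAULT_STITCH_DISTANCE
    fraction: float = 0.2
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    maf_max: float = 0.001
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"unparseable config file {path}: {exc}") from exc
        sim_raw = raw.pop("simulation", {})
        if "cohort_counts" in sim_raw:
            sim_raw["cohort_counts"] = {
                g: tuple(v) for g, v in sim_raw["cohort_counts"].items()
            }
        cfg = cls(**{k: v for k, v in raw.items() if k != "stages"})
        if "stages" in raw:
            cfg.stages = tuple(raw["stages"])
        seed = raw.get("seed", cfg.seed)
        sim_raw.setdefault("seed", seed)
        cfg.simulation = SimulationConfig(**sim_raw)
        cfg.seed = seed
        return cfg


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of human-readable issues; empty iff run_all may start."""
    issues = []
    if not (0 < config.fraction <= 1):
        issues.append(f"fraction: must be in (0, 1], got {config.fraction}")
    if config.stitch_distance < 0:
        issues.append(f"stitch_distance: must be >= 0, got {config.stitch_distance}")
    if config.fc_threshold <= 0:
        issues.append(f"fc_threshold: must be > 0, got {config.fc_threshold}")
    if not (0 < config.p_threshold <= 1):
        issues.append(f"p_threshold: must be in (0, 1], got {config.p_threshold}")
    if not (0 < config.maf_max < 1):
        issues.append(f"maf_max: must be in (0, 1), got {config.maf_max}")
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        issues.append(f"stages: unknown stage(s) {sorted(unknown)}")
    if "sim" not in config.stages:
        # without simulation every consuming stage needs its input on disk
        for stage, paths in _required_inputs(config).items():
            if stage in config.stages:
                for p in paths:
                    if not os.path.exists(p):
                        issues.append(f"{stage}: missing input {p}")
    try:
        config.simulation.validate()
    except ConfigurationError as exc:
        issues.append(str(exc))
    return issues


def _paths(config: PipelineConfig) -> dict[str, str]:
    d = config.outdir
    return {
        "genome_fa": os.path.join(d, "genome.fa"),
        "genes_tsv": os.path.join(d, "gene_models.tsv"),
        "truth_se_bed": os.path.join(d, "truth_se_regions.bed"),
        "peaks_bed": os.path.join(d, "h3k27ac_peaks.bed"),
        "signal_bdg": os.path.join(d, "h3k27ac_signal.bedGraph"),
        "fpkm_tsv": os.path.join(d, "fpkm.tsv"),
        "counts_tsv": os.path.join(d, "counts.tsv"),
        "cellmeta_tsv": os.path.join(d, "cell_metadata.tsv"),
        "fastq_nc": os.path.join(d, "3c_NC.fastq"),
        "fastq_kd": os.path.join(d, "3c_KD.fastq"),
        "cohort_tsv": os.path.join(d, "cohort.tsv"),
        "variants_tsv": os.path.join(d, "variants.tsv"),
        "list_snrna": os.path.join(d, "down_snrna.txt"),
        "list_bulk": os.path.join(d, "down_bulk.txt"),
        "list_se": os.path.join(d, "se_associated.txt"),
        "se_bed": os.path.join(d, "super_enhancers.bed"),
        "se_tsv": os.path.join(d, "se_rank_table.tsv"),
        "screen_tsv": os.path.join(d, "se_gene_screen.tsv"),
        "de_tsv": os.path.join(d, "sc_de.tsv"),
        "qc_json": os.path.join(d, "qc_report.json"),
        "venn_tsv": os.path.join(d, "venn_counts.tsv"),
        "intersection_txt": os.path.join(d, "intersection_genes.txt"),
        "profile_nc_bdg": os.path.join(d, "profile_NC.bedGraph"),
        "profile_kd_bdg": os.path.join(d, "profile_KD.bedGraph"),
        "tallies_tsv": os.path.join(d, "3c_tallies.tsv"),
        "comparison_tsv": os.path.join(d, "3c_region_comparison.tsv"),
        "chd_freq_tsv": os.path.join(d, "chd_frequency.tsv"),
        "variant_filter_tsv": os.path.join(d, "variants_retained.tsv"),
        "manifest_json": os.path.join(d, "manifest.json"),
    }


def _required_inputs(config: PipelineConfig) -> dict[str, list[str]]:
    p = _paths(config)
    return {
        "se_calling": [p["peaks_bed"], p["signal_bdg"]],
        "se_genes": [p["se_tsv"], p["genes_tsv"], p["fpkm_tsv"]],
        "sc_de": [p["counts_tsv"], p["cellmeta_tsv"]],
        "intersect": [p["list_snrna"], p["list_bulk"], p["list_se"]],
        "htgts3c": [p["genome_fa"], p["fastq_nc"], p["fastq_kd"]],
        "cohort": [p["cohort_tsv"], p["variants_tsv"]],
    }


@dataclass
class RunManifest:
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, inputs: list[str], outputs: list[str], params: dict):
        self.stages[stage] = {
            "inputs": sorted(inputs),
            "outputs": sorted(outputs),
            "params": params,
            "checksums": {os.path.basename(o): io.sha256_of(o) for o in sorted(outputs)},
        }

    def to_json(self) -> str:
        return json.dumps({"stages": self.stages}, indent=2, sort_keys=True)


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in pipeline order; abort on the first stage
    failure naming the stage, keeping partial outputs."""
    issues = validate_config(config)
    if issues:
        raise ConfigurationError("; ".join(issues))
    io.ensure_dir(config.outdir)
    p = _paths(config)
    manifest = RunManifest()
    genome = None

    def run_stage(name, fn):
        try:
            fn()
        except SeloopkitError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise SeloopkitError(f"stage {name} failed: {exc}") from exc

    if "sim" in config.stages:
        def _sim():
            nonlocal genome
            sim = config.simulation
            genome = generate_genome(sim)
            io.write_fasta(genome.sequences, p["genome_fa"])
            io.write_tsv(
                pd.DataFrame(
                    [
                        (g.gene_id, g.chrom, g.strand, g.tss, g.start, g.end)
                        for g in genome.gene_models
                    ],
                    columns=["gene_id", "chrom", "strand", "tss", "start", "end"],
                ),
                p["genes_tsv"],
            )
            io.write_bed(
                pd.DataFrame(
                    [(r.chrom, r.start, r.end, r.gene_id) for r in genome.truth_se_regions],
                    columns=["chrom", "start", "end", "name"],
                ),
                p["truth_se_bed"],
            )
            peaks, signal = simulate_chip_inputs(genome, sim)
            io.write_bed(peaks, p["peaks_bed"])
            io.write_bedgraph(signal, p["signal_bdg"])
            io.write_tsv(simulate_expression(genome, sim), p["fpkm_tsv"])
            matrix, _ = simulate_counts(sim)
            counts = pd.DataFrame(matrix.values, index=matrix.genes, columns=matrix.cells)
            counts.index.name = "gene_id"
            io.write_tsv(counts, p["counts_tsv"], index=True)
            meta = matrix.meta.copy()
            meta.index.name = "cell_id"
            io.write_tsv(meta, p["cellmeta_tsv"], index=True)
            for cond, path in (("NC", p["fastq_nc"]), ("KD", p["fastq_kd"])):
                reads, _ = simulate_3c_reads(genome, sim, condition=cond)
                io.write_fastq(reads, path)
            cohort, variants, _ = simulate_cohort_and_variants(sim)
            io.write_tsv(cohort, p["cohort_tsv"])
            io.write_tsv(variants.drop(columns=["planted_pass"]), p["variants_tsv"])
            for gs, path in zip(
                simulate_screen_gene_lists(sim.seed),
                (p["list_snrna"], p["list_bulk"], p["list_se"]),
            ):
                io.write_gene_list(sorted(gs.genes), path)
            manifest.record(
                "sim",
                [],
                [
                    p[k]
                    for k in (
                        "genome_fa", "genes_tsv", "truth_se_bed", "peaks_bed",
                        "signal_bdg", "fpkm_tsv", "counts_tsv", "cellmeta_tsv",
                        "fastq_nc", "fastq_kd", "cohort_tsv", "variants_tsv",
                        "list_snrna", "list_bulk", "list_se",
                    )
                ],
                dataclasses.asdict(sim),
            )
        run_stage("sim", _sim)

    if "se_calling" in config.stages:
        def _se():
            peaks_df = io.read_bed(p["peaks_bed"])
            peaks = [
                se_calling.EnhancerPeak(r.chrom, r.start, r.end, getattr(r, "name", ""))
                for r in peaks_df.itertuples(index=False)
            ]
            signal = se_calling.SignalTrack.from_bedgraph(p["signal_bdg"])
            stitched = se_calling.stitch_peaks(peaks, config.stitch_distance)
            scored = se_calling.score_stitched(stitched, signal)
            calls = se_calling.call_super_enhancers(scored)
            se_calling.write_se_outputs(calls, p["se_bed"], p["se_tsv"])
            manifest.record(
                "se_calling",
                [p["peaks_bed"], p["signal_bdg"]],
                [p["se_bed"], p["se_tsv"]],
                {"stitch_distance": config.stitch_distance},
            )
        run_stage("se_calling", _se)

    if "se_genes" in config.stages:
        def _genes():
            table = se_calling.read_se_table(p["se_tsv"])
            supers = table[table["is_super"]].copy()
            supers["se_id"] = [f"SE_{r}" for r in supers["rank"]]
            models = se_genes.gene_models_from_frame(io.read_tsv(p["genes_tsv"]))
            candidates, _ = se_genes.assign_nearest_gene(supers, models)
            fpkm = io.read_tsv(p["fpkm_tsv"])
            result = se_genes.expression_filter(candidates, fpkm, fraction=config.fraction)
            out = result.candidates.copy()
            out["selected"] = out["gene_id"].isin(set(result.selected["gene_id"]))
            io.write_tsv(out, p["screen_tsv"])
            manifest.record(
                "se_genes",
                [p["se_tsv"], p["genes_tsv"], p["fpkm_tsv"]],
                [p["screen_tsv"]],
                {"fraction": config.fraction},
            )
        run_stage("se_genes", _genes)

    if "sc_de" in config.stages:
        def _de():
            counts = io.read_tsv(p["counts_tsv"], index_col=0)
            meta = io.read_tsv(p["cellmeta_tsv"], index_col=0)
            matrix = sc_de.CountMatrix(
                values=counts.to_numpy(dtype=float),
                genes=list(counts.index),
                cells=list(counts.columns),
                meta=meta,
            )
            filtered, report = sc_de.qc_filter_cells(matrix)
            de = sc_de.bimod_test(filtered, "A", "B")
            io.write_tsv(de, p["de_tsv"])
            with open(p["qc_json"], "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
            manifest.record(
                "sc_de",
                [p["counts_tsv"], p["cellmeta_tsv"]],
                [p["de_tsv"], p["qc_json"]],
                {"fc_threshold": config.fc_threshold, "p_threshold": config.p_threshold},
            )
        run_stage("sc_de", _de)

    if "intersect" in config.stages:
        def _intersect():
            sets = [
                sc_de.GeneSet(label, frozenset(io.read_gene_list(path)))
                for label, path in (
                    ("snRNA_OFTL_down", p["list_snrna"]),
                    ("bulk_KD_down", p["list_bulk"]),
                    ("SE_associated", p["list_se"]),
                )
            ]
            inter, venn = sc_de.intersect_sets(sets)
            io.write_gene_list(sorted(inter.genes), p["intersection_txt"])
            venn_df = pd.DataFrame(
                sorted(venn.items()), columns=["membership", "count"]
            )
            io.write_tsv(venn_df, p["venn_tsv"])
            manifest.record(
                "intersect",
                [p["list_snrna"], p["list_bulk"], p["list_se"]],
                [p["intersection_txt"], p["venn_tsv"]],
                {},
            )
        run_stage("intersect", _intersect)

    if "htgts3c" in config.stages:
        def _3c():
            nonlocal genome
            sequences = io.read_fasta(p["genome_fa"])
            frag_map = htgts3c.digest_genome(sequences)
            if genome is not None:
                bait = bait_spec_for(genome)
                regions = [
                    (r.chrom, r.start, r.end) for r in genome.truth_se_regions
                ]
            else:
                raise ConfigurationError(
                    "htgts3c stage without sim stage requires a bait spec; "
                    "use the library API or enable the sim stage"
                )
            profiles = {}
            for cond, fq in (("NC", p["fastq_nc"]), ("KD", p["fastq_kd"])):
                reads = io.read_fastq(fq)
                profiles[cond] = htgts3c.profile_from_reads(reads, sequences, frag_map, bait)
            htgts3c.write_profile_bedgraph(profiles["NC"], p["profile_nc_bdg"])
            htgts3c.write_profile_bedgraph(profiles["KD"], p["profile_kd_bdg"])
            tallies = pd.DataFrame(
                [
                    {"condition": c, **profiles[c].tallies, "retained": profiles[c].total_retained}
                    for c in ("NC", "KD")
                ]
            )
            io.write_tsv(tallies, p["tallies_tsv"])
            rows = []
            for region in regions:
                cmp_ = htgts3c.compare_profiles(
                    profiles["NC"], profiles["KD"], region, seed=config.seed
                )
                rows.append(
                    {
                        "chrom": region[0], "start": region[1], "end": region[2],
                        "sum_nc": cmp_.sum_a, "sum_kd": cmp_.sum_b,
                        "ratio_kd_nc": cmp_.ratio,
                        "ci_low": cmp_.ci_low, "ci_high": cmp_.ci_high,
                    }
                )
            io.write_tsv(pd.DataFrame(rows), p["comparison_tsv"])
            manifest.record(
                "htgts3c",
                [p["genome_fa"], p["fastq_nc"], p["fastq_kd"]],
                [p["profile_nc_bdg"], p["profile_kd_bdg"], p["tallies_tsv"], p["comparison_tsv"]],
                {"normalization_scale": htgts3c.NORMALIZATION_SCALE},
            )
        run_stage("htgts3c", _3c)

    if "cohort" in config.stages:
        def _cohort():
            cohort = io.read_tsv(p["cohort_tsv"], keep_default_na=False)
            freq = cohort_variants.chd_frequency_by_gene(cohort)
            io.write_tsv(freq, p["chd_freq_tsv"])
            variants = io.read_tsv(p["variants_tsv"])
            coding = variants[variants["region_class"] == "coding"]
            retained, tallies = cohort_variants.filter_coding_variants(
                coding, cohort_variants.FilterCriteria(maf_max=config.maf_max)
            )
            noncoding = variants[variants["region_class"] != "coding"]
            retained_nc = cohort_variants.filter_noncoding_variants(
                noncoding, maf_max=config.maf_max
            )
            out = pd.concat([retained, retained_nc], ignore_index=True)
            io.write_tsv(out, p["variant_filter_tsv"])
            manifest.record(
                "cohort",
                [p["cohort_tsv"], p["variants_tsv"]],
                [p["chd_freq_tsv"], p["variant_filter_tsv"]],
                {"maf_max": config.maf_max, "exclusion_tallies": tallies},
            )
        run_stage("cohort", _cohort)

    with open(p["manifest_json"], "w") as fh:
        fh.write(manifest.to_json())
    return manifest
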