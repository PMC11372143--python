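"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the study system at desk scale: a small two-chromosome
genome with gene models and MboI (GATC) sites; constituent enhancer peaks
whose stitched signal is heavy-tailed, so the rank-signal curve is the convex
hockey stick that rank-ordering SE calling expects; an FPKM table in which
genes paired with planted super-enhancer clusters are boosted; zero-inflated
two-group count matrices with planted differential expression and planted
QC-violating cells; bait-anchored ligation reads carrying self-ligation,
religation and duplicate artifacts with super-enhancer contact enrichment and
a knockdown contact reduction; and curated cohort/variant tables.

Every generator derives its pseudo-random stream from (seed, generator name),
so the streams are independent and adding a generator never perturbs the
others. Fixed seed implies byte-identical outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .htgts3c import digest_genome, BaitSpec, RestrictionFragmentMap
from .sc_de import CountMatrix, GeneSet
from .se_genes import GeneModel

ADAPTER = "CTGTCTCTTATACACATCT"  # GATC-free so it never mimics a junction
PRIMER_LEN = 20
JUNCTION_WINDOW = 30  # bait-fragment bases retained between primer and junction

# Curated CdLS cohort counts per mutated cohesin gene:
# (n_patients, n_chd, n_chd_with_recorded_type, n_oft_type)
DEFAULT_COHORT_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "NIPBL": (217, 58, 58, 20),
    "RAD21": (43, 11, 11, 4),
    "SMC1A": (58, 14, 14, 5),
    "HDAC8": (49, 8, 8, 3),
    "SMC3": (42, 22, 21, 16),
}

# The four genes down-regulated in all three screens, plus named members of
# each individual screen list.
CORE_OVERLAP_GENES = ("Ankrd1", "Gadd45g", "Ets2", "Notch2")
SNRNA_NAMED = ("Tnnt2", "Tnnc1", "Myl1", "Myl4", "Myl9")
BULK_NAMED = ("Tbx1", "Tbx18", "Agt", "Mef2a")
SE_NAMED = ("Myh9", "Id1")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic-data generators.

    Defaults are the study conditions the pipeline is exercised under: 100
    cells per group with expression probability 0.5 and a planted log2 fold
    change of 2; 20-fold super-enhancer contact enrichment halved under
    knockdown; and the curated cohort counts.
    """

    seed: int = 0
    # genome / enhancers
    n_genes: int = 40
    n_enhancers: int = 40
    se_fraction: float = 0.1
    signal_tail_exponent: float = 3.0
    chrom_lengths: tuple[int, ...] = (500_000, 500_000)
    # expression
    fpkm_boost_for_se_genes: float = 10.0
    # single-nucleus counts
    n_cells_per_group: int = 100
    n_count_genes: int = 1000
    zero_inflation_pi: float = 0.5
    de_effect_log2fc: float = 2.0
    de_gene_fraction: float = 0.1
    qc_violation_fraction: float = 0.05
    expr_sigma: float = 1.0
    # 3C reads
    n_3c_reads: int = 20_000
    se_contact_enrichment: float = 10.0
    selflig_rate: float = 0.30
    relig_rate: float = 0.10
    dup_rate: float = 0.05
    kd_contact_ratio: float = 0.5
    read_length: int = 300  # merged mate pairs, sonication-sized molecules
    # cohort
    cohort_counts: dict[str, tuple[int, int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_COHORT_COUNTS)
    )

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ConfigurationError("n_genes must be >= 2")
        if self.n_enhancers < max(1, self.n_genes / 2):
            raise ConfigurationError("n_enhancers must be >= n_genes/2 and >= 1")
        for name in (
            "se_fraction",
            "zero_inflation_pi",
            "de_gene_fraction",
            "qc_violation_fraction",
            "selflig_rate",
            "relig_rate",
            "dup_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 < self.kd_contact_ratio <= 1.0):
            raise ConfigurationError("kd_contact_ratio must be in (0, 1]")
        if self.selflig_rate + self.relig_rate > 1.0:
            raise ConfigurationError("selflig_rate + relig_rate must not exceed 1")
        if self.n_cells_per_group < 20:
            raise ConfigurationError("n_cells_per_group must be >= 20")
        if self.se_contact_enrichment <= 0:
            raise ConfigurationError("se_contact_enrichment must be > 0")
        if self.signal_tail_exponent <= 0:
            raise ConfigurationError("signal_tail_exponent must be > 0")
        if self.fpkm_boost_for_se_genes <= 0:
            raise ConfigurationError("fpkm_boost_for_se_genes must be > 0")
        for gene, counts in self.cohort_counts.items():
            n_pat, n_chd, n_typed, n_oft = counts
            if not (0 <= n_chd <= n_pat):
                raise ConfigurationError(f"cohort_counts[{gene}]: n_chd > n_patients")
            if not (0 <= n_typed <= n_chd):
                raise ConfigurationError(f"cohort_counts[{gene}]: n_typed > n_chd")
            if not (0 <= n_oft <= n_typed):
                raise ConfigurationError(f"cohort_counts[{gene}]: n_oft_type > n_typed")


def _rng(config: SimulationConfig, name: str) -> np.random.Generator:
    """One independent stream per (seed, generator name)."""
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng([config.seed, key])


@dataclass(frozen=True)
class TruthEnhancer:
    chrom: str
    start: int
    end: int
    height: float
    cluster_id: int
    is_se: bool


@dataclass(frozen=True)
class TruthSERegion:
    chrom: str
    start: int
    end: int
    gene_id: str
    cluster_id: int


@dataclass
class SyntheticGenome:
    chrom_names: list[str]
    sequences: dict[str, str]
    gene_models: list[GeneModel]
    truth_enhancers: list[TruthEnhancer]
    truth_se_regions: list[TruthSERegion]
    bait: tuple[str, int, int]  # the bait restriction fragment interval
    se_gene_ids: list[str]

    def fragment_map(self) -> RestrictionFragmentMap:
        return digest_genome(self.sequences)


def generate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Lay out gene/enhancer-cluster units along the chromosomes.

    Each unit is a 2 kb gene followed by a cluster of 2-4 constituent
    enhancers a few kb downstream; inter-unit gaps stay above the default
    stitch distance so clusters never merge. A fraction of gene-paired
    clusters is designated super-enhancer and given heavy-tailed signal
    heights; the planted SE region is its cluster's bounding interval, and the
    paired gene is the planted SE-associated gene. The bait is the MboI
    fragment containing the first gene's TSS.
    """
    config.validate()
    rng = _rng(config, "genome")
    chrom_names = [f"chr{i + 1}" for i in range(len(config.chrom_lengths))]
    sequences = {
        name: "".join(rng.choice(list("ACGT"), size=length))
        for name, length in zip(chrom_names, config.chrom_lengths)
    }

    n_units = config.n_enhancers
    per_chrom = int(np.ceil(n_units / len(chrom_names)))
    n_se = int(round(config.se_fraction * n_units)) if config.se_fraction > 0 else 0
    n_se = min(n_se, config.n_genes)  # SE clusters must have a paired gene
    # choose SE clusters among gene-paired ones, never the bait unit (unit 0
    # hosts the bait promoter; keeping it typical keeps the bait fragment
    # outside every SE region)
    paired = [u for u in range(1, min(config.n_genes, n_units))]
    se_units = set(rng.choice(paired, size=n_se, replace=False)) if n_se else set()

    gene_models: list[GeneModel] = []
    enhancers: list[TruthEnhancer] = []
    se_regions: list[TruthSERegion] = []
    se_gene_ids: list[str] = []

    unit = 0
    for chrom in chrom_names:
        cursor = int(rng.integers(2_000, 4_000))
        length = len(sequences[chrom])
        for _ in range(per_chrom):
            if unit >= n_units:
                break
            gene_id = f"gene{unit:03d}" if unit < config.n_genes else None
            gene_span = 2_000
            if gene_id is not None:
                strand = "+" if rng.random() < 0.5 else "-"
                g_start = cursor
                g_end = g_start + gene_span
                tss = g_start if strand == "+" else g_end - 1
                if g_end >= length:
                    break
                gene_models.append(GeneModel(gene_id, chrom, strand, tss, g_start, g_end))
                cursor = g_end + int(rng.integers(2_000, 5_000))
            n_const = int(rng.integers(2, 5))
            is_se = unit in se_units
            c_start = cursor
            last_end = cursor
            if is_se:
                base = 30.0 * (1.0 + rng.pareto(config.signal_tail_exponent))
            for k in range(n_const):
                width = int(rng.integers(400, 800))
                if is_se:
                    height = base * rng.uniform(0.8, 1.2)
                else:
                    height = rng.gamma(2.0, 1.5) + 0.5
                start = last_end if k == 0 else last_end + int(rng.integers(300, 800))
                end = start + width
                if end >= length:
                    break
                enhancers.append(TruthEnhancer(chrom, start, end, height, unit, is_se))
                last_end = end
            cluster_members = [e for e in enhancers if e.cluster_id == unit]
            if is_se and cluster_members and gene_id is not None:
                se_regions.append(
                    TruthSERegion(
                        chrom,
                        min(e.start for e in cluster_members),
                        max(e.end for e in cluster_members),
                        gene_id,
                        unit,
                    )
                )
                se_gene_ids.append(gene_id)
            cursor = last_end + int(rng.integers(13_500, 16_500))
            unit += 1
            if cursor >= length:
                break

    # leftover genes beyond the laid-out units (n_genes > n_units): place on
    # the last chromosome tail
    while len(gene_models) < config.n_genes:
        gene_id = f"gene{len(gene_models):03d}"
        chrom = chrom_names[-1]
        length = len(sequences[chrom])
        g_start = int(rng.integers(0, length - 2_001))
        gene_models.append(GeneModel(gene_id, chrom, "+", g_start, g_start, g_start + 2_000))

    # bait: the MboI fragment containing gene0's TSS, long enough for the
    # primer + junction window
    frag_map = digest_genome(sequences)
    bait_gene = gene_models[0]
    idx = frag_map.fragment_index(bait_gene.chrom, bait_gene.tss)
    n_frag = frag_map.n_fragments(bait_gene.chrom)
    min_len = PRIMER_LEN + JUNCTION_WINDOW + 4
    offset = 0
    found = None

    def neighbours_mappable(cand: int) -> bool:
        # religation partners (the two adjacent fragments) must be long
        # enough to anchor the exact mapper
        for nb in (cand - 1, cand + 1):
            if 0 <= nb < n_frag:
                s, e = frag_map.fragment(bait_gene.chrom, nb)
                if e - s < 24:
                    return False
        return True

    while found is None and offset < n_frag:
        for cand in (idx - offset, idx + offset):
            if 0 <= cand < n_frag:
                s, e = frag_map.fragment(bait_gene.chrom, cand)
                if e - s >= min_len and neighbours_mappable(cand):
                    found = (bait_gene.chrom, s, e)
                    break
        offset += 1
    if found is None:
        raise ConfigurationError("chrom_lengths too small: no fragment can host the bait")

    return SyntheticGenome(
        chrom_names=chrom_names,
        sequences=sequences,
        gene_models=gene_models,
        truth_enhancers=enhancers,
        truth_se_regions=se_regions,
        bait=found,
        se_gene_ids=se_gene_ids,
    )


def simulate_chip_inputs(
    genome: SyntheticGenome, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit constituent peaks (BED-like frame) and an H3K27ac signal track
    (bedGraph-like frame): each truth enhancer emits one peak and one signal
    interval at its planted height over a low noise background."""
    if not genome.truth_enhancers:
        raise ConfigurationError("genome has no truth_enhancers")
    rng = _rng(config, "chip")
    peak_rows = []
    for i, e in enumerate(genome.truth_enhancers):
        peak_rows.append((e.chrom, e.start, e.end, f"peak{i:04d}"))
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "name"])

    signal_rows = []
    bin_size = 1_000
    by_chrom: dict[str, list[TruthEnhancer]] = {c: [] for c in genome.chrom_names}
    for e in genome.truth_enhancers:
        by_chrom[e.chrom].append(e)
    for chrom in genome.chrom_names:
        length = len(genome.sequences[chrom])
        cursor = 0
        for e in sorted(by_chrom[chrom], key=lambda e: e.start):
            pos = cursor
            while pos < e.start:  # background bins up to the peak
                end = min(pos + bin_size, e.start)
                signal_rows.append((chrom, pos, end, rng.gamma(1.0, 0.2)))
                pos = end
            signal_rows.append((chrom, e.start, e.end, e.height * rng.uniform(0.95, 1.05)))
            cursor = e.end
        pos = cursor
        while pos < length:
            end = min(pos + bin_size, length)
            signal_rows.append((chrom, pos, end, rng.gamma(1.0, 0.2)))
            pos = end
    signal = pd.DataFrame(signal_rows, columns=["chrom", "start", "end", "value"])
    return peaks, signal


def _draw_fpkm(
    n: int, se_mask: np.ndarray, boost: float, rng: np.random.Generator
) -> np.ndarray:
    base = rng.lognormal(mean=2.0, sigma=1.0, size=n)
    return base * np.where(se_mask, boost, 1.0)


def simulate_expression(genome: SyntheticGenome, config: SimulationConfig) -> pd.DataFrame:
    """FPKM table over the genome's genes; genes paired with planted SE
    regions get their FPKM multiplied by ``fpkm_boost_for_se_genes``."""
    rng = _rng(config, "expression")
    gene_ids = [g.gene_id for g in genome.gene_models]
    se_mask = np.array([g in set(genome.se_gene_ids) for g in gene_ids])
    fpkm = _draw_fpkm(len(gene_ids), se_mask, config.fpkm_boost_for_se_genes, rng)
    return pd.DataFrame({"gene_id": gene_ids, "fpkm": fpkm})


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, dict]:
    """Zero-inflated two-group expression matrix with planted DE.

    Per gene, a cell expresses with probability pi; expressed values are
    expm1 of a Normal on the log scale, whose mean is shifted down by
    ``de_effect_log2fc`` (in log2 units) in group B for the planted DE genes.
    A ``qc_violation_fraction`` of cells violates the QC rules (about half
    with <= 200 detected genes, half with mitochondrial fraction >= 25%).
    Returns the matrix plus a truth dict (de gene ids, QC-fail cell ids).
    """
    config.validate()
    rng = _rng(config, "counts")
    G = config.n_count_genes
    n_per = config.n_cells_per_group
    n_cells = 2 * n_per
    genes = [f"cg{i:04d}" for i in range(G)]
    cells = [f"cell{i:04d}" for i in range(n_cells)]
    group = np.array(["A"] * n_per + ["B"] * n_per)

    n_de = int(np.floor(config.de_gene_fraction * G))
    de_idx = rng.choice(G, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    de_mask = np.zeros(G, dtype=bool)
    de_mask[de_idx] = True

    base_mu = rng.normal(1.5, 0.5, size=G)
    mu = np.tile(base_mu[:, None], (1, n_cells))
    shift = config.de_effect_log2fc * np.log(2.0)
    mu[np.ix_(de_mask, group == "B")] -= shift

    expressed = rng.random((G, n_cells)) < config.zero_inflation_pi
    # expressed log-values ~ Normal(mu, sigma) truncated to (0, inf) so an
    # "expressed" draw is always positive and the zero mass equals 1 - pi
    from scipy.stats import norm

    lo = norm.cdf(-mu / config.expr_sigma)
    u = lo + rng.random((G, n_cells)) * (1.0 - lo)
    logvals = mu + config.expr_sigma * norm.ppf(u)
    values = np.where(expressed, np.expm1(np.maximum(logvals, 1e-9)), 0.0)

    n_viol = int(round(config.qc_violation_fraction * n_cells))
    viol_idx = rng.choice(n_cells, size=n_viol, replace=False) if n_viol else np.array([], dtype=int)
    mito = rng.uniform(0.0, 0.20, size=n_cells)
    qc_fail = np.zeros(n_cells, dtype=bool)
    for j, cell in enumerate(viol_idx):
        qc_fail[cell] = True
        if j % 2 == 0:  # low-complexity cell: exactly 150 detected genes
            keep = rng.choice(G, size=150, replace=False)
            col = np.zeros(G)
            col[keep] = np.maximum(values[keep, cell], 1.0)
            values[:, cell] = col
        else:  # high mitochondrial content
            mito[cell] = rng.uniform(0.25, 0.60)

    meta = pd.DataFrame(
        {
            "group": group,
            "n_genes_detected": (values > 0).sum(axis=0),
            "mito_fraction": mito,
            "planted_qc_fail": qc_fail,
        },
        index=cells,
    )
    matrix = CountMatrix(values=values, genes=genes, cells=cells, meta=meta)
    truth = {
        "de_genes": [genes[i] for i in np.flatnonzero(de_mask)],
        "qc_fail_cells": [cells[i] for i in np.flatnonzero(qc_fail)],
    }
    return matrix, truth


def bait_spec_for(genome: SyntheticGenome) -> BaitSpec:
    """Nested-primer spec anchored in the genome's bait fragment: the primer
    is the 20-mer ending ``JUNCTION_WINDOW`` bases before the fragment end."""
    chrom, start, end = genome.bait
    frag_map = genome.fragment_map()
    idx = frag_map.fragment_index(chrom, start)
    L = end - start
    if L < PRIMER_LEN + JUNCTION_WINDOW + 4:
        raise ConfigurationError("bait fragment shorter than primer + junction window")
    seq = genome.sequences[chrom][start:end]
    primer = seq[L - JUNCTION_WINDOW - PRIMER_LEN : L - JUNCTION_WINDOW]
    return BaitSpec(chrom=chrom, fragment_index=idx, nested_primer=primer, adapter=ADAPTER)


def simulate_3c_reads(
    genome: SyntheticGenome, config: SimulationConfig, condition: str = "NC"
) -> tuple[list[tuple[str, str]], dict]:
    """Bait-anchored junction reads.

    Each read emulates a merged mate pair off a sonicated proximity-ligation
    concatemer: nested-primer + the bait-fragment tail up to the junction +
    the partner fragment's GATC-leading sequence, read through into a further
    ligated fragment when the sonication breakpoint lies beyond the partner,
    then adapter — truncated to the read length. The variable breakpoint and
    read-through partner make independent molecules to the same fragment
    distinguishable, as in real libraries. Partners are sampled uniformly
    over background fragments and at ``se_contact_enrichment``-fold weight
    over fragments inside planted SE regions; under condition "KD" the SE
    weight is multiplied by ``kd_contact_ratio``. ``selflig_rate`` of reads
    rejoin the bait fragment, ``relig_rate`` a bait-adjacent fragment, and
    ``dup_rate`` are exact duplicates of earlier valid-partner reads.
    Returns (reads, truth tallies).
    """
    config.validate()
    if condition not in {"NC", "KD"}:
        raise ConfigurationError(f"condition must be NC or KD, got {condition!r}")
    rng = _rng(config, f"3c_{condition}")
    frag_map = genome.fragment_map()
    bait = bait_spec_for(genome)
    chromb = bait.chrom
    bait_idx = bait.fragment_index
    bstart, bend = frag_map.fragment(chromb, bait_idx)
    bait_tail = genome.sequences[chromb][bend - JUNCTION_WINDOW : bend]
    prefix = bait.nested_primer + bait_tail

    # partner pool: every fragment except bait and its neighbours, long
    # enough to map (>= EXACT_MAP_K bases)
    pool: list[tuple[str, int]] = []
    weights: list[float] = []
    se_frag_keys: set[tuple[str, int]] = set()
    for r in genome.truth_se_regions:
        for i in frag_map.overlapping(r.chrom, r.start, r.end):
            se_frag_keys.add((r.chrom, i))
    se_weight = config.se_contact_enrichment
    if condition == "KD":
        se_weight *= config.kd_contact_ratio
    for chrom, i, s, e in frag_map.iter_fragments():
        if chrom == chromb and abs(i - bait_idx) <= 1:
            continue
        if e - s < 24:
            continue
        pool.append((chrom, i))
        weights.append(se_weight if (chrom, i) in se_frag_keys else 1.0)
    w = np.asarray(weights)
    w = w / w.sum()

    budget = config.read_length - len(prefix) - len(ADAPTER)
    if budget < 24:
        raise ConfigurationError("read_length too short for primer + junction + partner")
    all_frags = list(frag_map.iter_fragments())

    n = config.n_3c_reads
    partner_draws = rng.choice(len(pool), size=n, p=w)
    category_u = rng.random(n)
    dup_u = rng.random(n)
    dup_src = rng.integers(0, max(n, 1), size=n)
    breakpoints = rng.integers(24, budget + 1, size=n)  # sonication breakpoint
    readthrough = rng.integers(0, len(all_frags), size=n)
    adj = [i for i in (bait_idx - 1, bait_idx + 1) if 0 <= i < frag_map.n_fragments(chromb)]
    adj_pick = rng.integers(0, max(len(adj), 1), size=n)

    def partner_portion(chrom: str, i: int, bp: int, rt: int) -> str:
        s, e = frag_map.fragment(chrom, i)
        portion = genome.sequences[chrom][s:e]
        while len(portion) < bp:  # molecule continues into further ligated fragments
            c2, _, s2, e2 = all_frags[rt]
            portion += genome.sequences[c2][s2:e2]
            rt = (rt + 1) % len(all_frags)
        return portion[:bp]

    reads: list[tuple[str, str]] = []
    valid_reads: list[str] = []
    truth = {"self_ligation": 0, "religation": 0, "duplicate": 0, "se_partner": 0, "bg_partner": 0}
    for i in range(n):
        if valid_reads and dup_u[i] < config.dup_rate:
            reads.append((f"r{i:06d}", valid_reads[int(dup_src[i]) % len(valid_reads)]))
            truth["duplicate"] += 1
            continue
        u = category_u[i]
        valid = False
        if u < config.selflig_rate:
            partner = (chromb, bait_idx)
            truth["self_ligation"] += 1
        elif u < config.selflig_rate + config.relig_rate and adj:
            partner = (chromb, adj[int(adj_pick[i])])
            truth["religation"] += 1
        else:
            partner = pool[int(partner_draws[i])]
            valid = True
            if partner in se_frag_keys:
                truth["se_partner"] += 1
            else:
                truth["bg_partner"] += 1
        portion = partner_portion(*partner, int(breakpoints[i]), int(readthrough[i]))
        seq = (prefix + portion + ADAPTER)[: config.read_length]
        reads.append((f"r{i:06d}", seq))
        if valid:
            valid_reads.append(seq)
    return reads, truth


def simulate_cohort_and_variants(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Curated cohort table plus an annotated variant table with planted
    pass/fail variants for every filter clause.

    Emitted per-gene patient counts equal ``cohort_counts`` exactly. The truth
    dict lists the variant ids expected to survive the coding and noncoding
    filters and the per-rule planted fail counts.
    """
    config.validate()
    rng = _rng(config, "cohort")
    rows = []
    pid = 0
    oft_types = ["TOF", "TGA", "PA dysplasia", "DORV"]
    other_types = ["VSD", "ASD", "PDA", "PS"]
    for gene, (n_pat, n_chd, n_typed, n_oft) in sorted(config.cohort_counts.items()):
        for j in range(n_pat):
            pid += 1
            chd = j < n_chd
            if chd and j < n_typed:
                if j < n_oft:
                    ctype, oft = oft_types[j % len(oft_types)], True
                else:
                    ctype, oft = other_types[j % len(other_types)], False
            else:
                ctype, oft = "", False
            rows.append((f"P{pid:04d}", gene, chd, ctype, oft))
    cohort = pd.DataFrame(
        rows, columns=["patient_id", "gene", "chd_status", "chd_type", "oft_type"]
    )
    cohort = cohort.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(
        drop=True
    )

    # planted variant panel: one row per filter clause, pass and fail
    panel = [
        # vid, region, consequence, gnomad, exac, sift, polyphen, cadd, reg, splice, mirna, passes
        ("v_syn", "coding", "synonymous", 0.0, 0.0, "T", "B", 5.0, 0, 0, 0, False),
        ("v_common_mis", "coding", "missense", 0.005, 0.002, "D", "D", 25.0, 0, 0, 0, False),
        ("v_one_alg", "coding", "missense", 0.0, 0.0, "D", "B", 10.0, 0, 0, 0, False),
        ("v_cadd_only", "coding", "missense", 0.0, 0.0, "T", "B", 21.0, 0, 0, 0, False),
        ("v_pass_mis", "coding", "missense", 0.0005, 0.0, "D", "D", 25.0, 0, 0, 0, True),
        ("v_pass_mis2", "coding", "missense", 0.0, 0.0, "T", "P", 22.0, 0, 0, 0, True),
        ("v_nonsense", "coding", "nonsense", 0.0, 0.0, "T", "B", 35.0, 0, 0, 0, True),
        ("v_frameshift", "coding", "frameshift", 0.0002, 0.0, "T", "B", 30.0, 0, 0, 0, True),
        ("v_promoter", "promoter/5'UTR", "regulatory", 0.0, 0.0, "", "", 0.0, 1, 0, 0, True),
        ("v_intron_null", "intronic", "intronic", 0.0, 0.0, "", "", 0.0, 0, 0, 0, False),
        ("v_utr_common", "3'UTR", "utr", 0.01, 0.0, "", "", 0.0, 0, 0, 1, False),
        ("v_splice", "intronic", "splice_region", 0.0003, 0.0, "", "", 0.0, 0, 1, 0, True),
    ]
    variants = pd.DataFrame(
        panel,
        columns=[
            "variant_id",
            "region_class",
            "consequence",
            "maf_gnomad",
            "maf_exac",
            "sift_call",
            "polyphen2_call",
            "cadd_phred",
            "regulatory_flag",
            "splice_flag",
            "mirna_flag",
            "planted_pass",
        ],
    )
    variants = variants.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(
        drop=True
    )
    coding = variants[variants["region_class"] == "coding"]
    noncoding = variants[variants["region_class"] != "coding"]
    truth = {
        "coding_pass": sorted(coding.loc[coding["planted_pass"], "variant_id"]),
        "noncoding_pass": sorted(noncoding.loc[noncoding["planted_pass"], "variant_id"]),
        "coding_fail_by_rule": {"synonymous": 1, "maf": 1, "deleteriousness": 2},
    }
    return cohort, variants, truth


def simulate_screen_gene_lists(seed: int = 0) -> tuple[GeneSet, GeneSet, GeneSet]:
    """Synthetic stand-in for the three down-gene screen lists.

    Builds the single-nucleus OFT cardiomyocyte down list (4628 symbols), the
    bulk knockdown down list (730) and the SE-associated list (308) so that
    their exact three-way intersection is the four overlap genes (Ankrd1,
    Gadd45g, Ets2, Notch2). Named cardiac genes from each screen are included
    in their respective lists, filler symbols are disjoint, and a small number
    of pairwise-only overlaps is planted for realism.
    """
    rng = np.random.default_rng([seed, 0x5E11])
    core = list(CORE_OVERLAP_GENES)
    ab_only = [f"Shab{i:03d}" for i in range(40)]  # snRNA & bulk, not SE list
    ac_only = [f"Shac{i:03d}" for i in range(25)]  # snRNA & SE list, not bulk
    bc_only = [f"Shbc{i:03d}" for i in range(10)]  # bulk & SE list, not snRNA

    def pad(prefix: str, members: list[str], size: int) -> list[str]:
        fillers = [f"{prefix}{i:04d}" for i in range(size - len(members))]
        out = members + fillers
        rng.shuffle(out)
        return out

    list_a = pad("Snr", core + list(SNRNA_NAMED) + ab_only + ac_only, 4628)
    list_b = pad("Blk", core + list(BULK_NAMED) + ab_only + bc_only, 730)
    list_c = pad("Sea", core + list(SE_NAMED) + ac_only + bc_only, 308)
    return (
        GeneSet("snRNA_OFTL_down", frozenset(list_a), "synthetic stand-in"),
        GeneSet("bulk_KD_down", frozenset(list_b), "synthetic stand-in"),
        GeneSet("SE_associated", frozenset(list_c), "synthetic stand-in"),
    )
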