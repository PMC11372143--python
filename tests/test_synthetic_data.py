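"""Generator determinism, configuration validation, and truth round-trips."""

import numpy as np
import pytest
from scipy import stats

from seloopkit import htgts3c as h3c, synthetic_data as sd
from seloopkit.errors import ConfigurationError


class TestConfigValidation:
    def test_zero_enhancers_rejected_naming_field(self):
        with pytest.raises(ConfigurationError, match="n_enhancers"):
            sd.generate_genome(sd.SimulationConfig(n_enhancers=0))

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"kd_contact_ratio": 0.0}, "kd_contact_ratio"),
            ({"selflig_rate": 1.2}, "selflig_rate"),
            ({"n_cells_per_group": 5}, "n_cells_per_group"),
            ({"se_contact_enrichment": -1}, "se_contact_enrichment"),
        ],
    )
    def test_invalid_fields_named(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            sd.SimulationConfig(**kwargs).validate()

    def test_inconsistent_cohort_counts_rejected(self):
        cfg = sd.SimulationConfig(cohort_counts={"SMC3": (42, 22, 21, 30)})  # oft > typed
        with pytest.raises(ConfigurationError, match="SMC3"):
            sd.simulate_cohort_and_variants(cfg)


class TestDeterminism:
    def test_genome_byte_identical_under_seed(self):
        a = sd.generate_genome(sd.SimulationConfig(seed=6))
        b = sd.generate_genome(sd.SimulationConfig(seed=6))
        assert a.sequences == b.sequences
        assert a.gene_models == b.gene_models
        assert a.truth_enhancers == b.truth_enhancers
        assert a.bait == b.bait

    def test_every_generator_reproducible(self, genome, sim_config):
        p1, s1 = sd.simulate_chip_inputs(genome, sim_config)
        p2, s2 = sd.simulate_chip_inputs(genome, sim_config)
        assert p1.equals(p2) and s1.equals(s2)
        assert sd.simulate_expression(genome, sim_config).equals(
            sd.simulate_expression(genome, sim_config)
        )
        m1, t1 = sd.simulate_counts(sim_config)
        m2, t2 = sd.simulate_counts(sim_config)
        assert np.array_equal(m1.values, m2.values) and t1 == t2
        r1, tr1 = sd.simulate_3c_reads(genome, sim_config, "NC")
        r2, tr2 = sd.simulate_3c_reads(genome, sim_config, "NC")
        assert r1 == r2 and tr1 == tr2
        c1, v1, _ = sd.simulate_cohort_and_variants(sim_config)
        c2, v2, _ = sd.simulate_cohort_and_variants(sim_config)
        assert c1.equals(c2) and v1.equals(v2)

    def test_different_seeds_differ(self):
        a = sd.generate_genome(sd.SimulationConfig(seed=1))
        b = sd.generate_genome(sd.SimulationConfig(seed=2))
        assert a.sequences != b.sequences


class TestGenome:
    def test_digestion_yields_multiple_fragments_per_chromosome(self, genome):
        fm = genome.fragment_map()
        for chrom in genome.chrom_names:
            assert fm.n_fragments(chrom) >= 2

    def test_gene_spans_within_bounds_and_se_regions_inside_enhancer_union(self, genome):
        for g in genome.gene_models:
            assert 0 <= g.start < g.end <= len(genome.sequences[g.chrom])
        enh_by_cluster = {}
        for e in genome.truth_enhancers:
            enh_by_cluster.setdefault(e.cluster_id, []).append(e)
        for r in genome.truth_se_regions:
            members = enh_by_cluster[r.cluster_id]
            assert all(m.is_se for m in members)
            assert r.start == min(m.start for m in members)
            assert r.end == max(m.end for m in members)

    def test_bait_is_a_valid_fragment(self, genome):
        fm = genome.fragment_map()
        chrom, start, end = genome.bait
        idx = fm.fragment_index(chrom, start)
        assert fm.fragment(chrom, idx) == (start, end)
        assert end - start >= sd.PRIMER_LEN + sd.JUNCTION_WINDOW + 4


class TestChipInputs:
    def test_each_truth_enhancer_emits_a_peak(self, genome, sim_config, chip_inputs):
        peaks, _ = chip_inputs
        got = set(zip(peaks["chrom"], peaks["start"], peaks["end"]))
        for e in genome.truth_enhancers:
            assert (e.chrom, e.start, e.end) in got

    def test_signal_track_sorted_nonoverlapping_nonnegative(self, chip_inputs):
        _, signal = chip_inputs
        for _, sub in signal.groupby("chrom"):
            starts, ends = sub["start"].to_numpy(), sub["end"].to_numpy()
            assert (starts[1:] >= ends[:-1]).all()
            assert (sub["value"] >= 0).all()

    def test_se_fraction_zero_leaves_no_heavy_tail(self):
        cfg = sd.SimulationConfig(seed=8, se_fraction=0.0)
        g = sd.generate_genome(cfg)
        assert g.truth_se_regions == []
        heights = [e.height for e in g.truth_enhancers]
        assert max(heights) < 20  # gamma background, no heavy-tail draw


class TestExpression:
    def test_boost_one_is_null(self):
        rng = np.random.default_rng(7)
        mask = np.zeros(1000, dtype=bool)
        mask[:100] = True
        vals = sd._draw_fpkm(1000, mask, 1.0, rng)
        assert stats.mannwhitneyu(vals[mask], vals[~mask]).pvalue > 0.01

    def test_boosted_se_genes_reach_top_quantile(self, genome, sim_config):
        fpkm = sd.simulate_expression(genome, sim_config)
        assert (fpkm["fpkm"] >= 0).all()
        top = set(fpkm.nlargest(int(0.2 * len(fpkm)), "fpkm")["gene_id"])
        frac = len(set(genome.se_gene_ids) & top) / len(genome.se_gene_ids)
        assert frac >= 0.8


class TestCounts:
    def test_planted_low_complexity_cells_violate_qc(self):
        cfg = sd.SimulationConfig(seed=9, n_count_genes=600, n_cells_per_group=40)
        matrix, truth = sd.simulate_counts(cfg)
        meta = matrix.meta
        for cell in truth["qc_fail_cells"]:
            row = meta.loc[cell]
            assert row["n_genes_detected"] <= 200 or row["mito_fraction"] >= 0.25

    def test_zero_inflation_matches_pi(self):
        cfg = sd.SimulationConfig(seed=10, n_count_genes=500, qc_violation_fraction=0.0)
        matrix, _ = sd.simulate_counts(cfg)
        expressed = (matrix.values > 0).mean()
        assert abs(expressed - cfg.zero_inflation_pi) < 0.02


class TestReads3C:
    def test_all_self_ligation_filters_to_empty(self, genome, fragment_map, bait):
        cfg = sd.SimulationConfig(seed=1, selflig_rate=1.0, relig_rate=0.0, dup_rate=0.0,
                                  n_3c_reads=500)
        reads, truth = sd.simulate_3c_reads(genome, cfg, "NC")
        assert truth["self_ligation"] == 500
        with pytest.warns(UserWarning):
            profile = h3c.profile_from_reads(reads, genome.sequences, fragment_map, bait)
        assert profile.total_retained == 0

    def test_read_too_short_for_bait_rejected(self, genome):
        cfg = sd.SimulationConfig(seed=1, read_length=60)
        with pytest.raises(ConfigurationError):
            sd.simulate_3c_reads(genome, cfg, "NC")

    def test_artifact_tallies_round_trip(self, genome, fragment_map, bait, sim_config):
        reads, truth = sd.simulate_3c_reads(genome, sim_config, "NC")
        profile = h3c.profile_from_reads(reads, genome.sequences, fragment_map, bait)
        assert profile.tallies["self_ligation"] == truth["self_ligation"]
        assert profile.tallies["religation"] == truth["religation"]
        # planted duplicates are all caught; a few incidental molecule
        # collisions may add to the tally
        assert truth["duplicate"] <= profile.tallies["duplicate"] <= int(truth["duplicate"] * 1.25)

    def test_se_fragments_enriched_over_background(self, genome, fragment_map, bait, sim_config):
        reads, _ = sd.simulate_3c_reads(genome, sim_config, "NC")
        profile = h3c.profile_from_reads(reads, genome.sequences, fragment_map, bait)
        se_frags = set()
        for r in genome.truth_se_regions:
            se_frags.update((r.chrom, i) for i in fragment_map.overlapping(r.chrom, r.start, r.end))
        norm = profile.normalized
        se_mean = sum(v for k, v in norm.items() if k in se_frags) / len(se_frags)
        bg_mean = sum(v for k, v in norm.items() if k not in se_frags) / (
            fragment_map.n_fragments() - len(se_frags)
        )
        assert se_mean / bg_mean >= 5.0

    def test_unit_enrichment_profile_is_flat(self):
        cfg = sd.SimulationConfig(seed=3, se_contact_enrichment=1.0,
                                  selflig_rate=0.0, relig_rate=0.0, dup_rate=0.0)
        g = sd.generate_genome(cfg)
        fm = g.fragment_map()
        bait = sd.bait_spec_for(g)
        reads, _ = sd.simulate_3c_reads(g, cfg, "NC")
        profile = h3c.profile_from_reads(reads, g.sequences, fm, bait)
        eligible = [
            (c, i) for c, i, s, e in fm.iter_fragments()
            if e - s >= 24 and not (c == bait.chrom and abs(i - bait.fragment_index) <= 1)
        ]
        counts = np.array([profile.raw_counts.get(k, 0) for k in eligible])
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert stats.chi2.sf(chi2, len(counts) - 1) > 0.01


class TestCohortGenerator:
    def test_counts_tally_back_exactly(self):
        cohort, _, _ = sd.simulate_cohort_and_variants(sd.SimulationConfig(seed=4))
        smc3 = cohort[cohort["gene"] == "SMC3"]
        assert len(smc3) == 42
        assert smc3["chd_status"].sum() == 22
        typed = smc3[smc3["chd_type"] != ""]
        assert len(typed) == 21
        assert typed["oft_type"].sum() == 16

    def test_screen_lists_have_reported_sizes(self):
        a, b, c = sd.simulate_screen_gene_lists(seed=1)
        assert (len(a), len(b), len(c)) == (4628, 730, 308)
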