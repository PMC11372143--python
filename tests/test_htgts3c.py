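"""In-silico digestion, junction-read preprocessing, fragment assignment,
artifact filtering, normalization and profile comparison."""

import numpy as np
import pytest

from seloopkit import htgts3c as h3c, io
from seloopkit.errors import InputError


def frags(fm, chrom):
    b = fm.fragments[chrom]
    return [(int(b[i]), int(b[i + 1])) for i in range(len(b) - 1)]


class TestDigestion:
    def test_manual_scan_example(self):
        fm = h3c.digest_genome({"c": "AAGATCCCGATCAA"})
        assert frags(fm, "c") == [(0, 2), (2, 8), (8, 14)]

    def test_no_site_yields_single_fragment(self):
        fm = h3c.digest_genome({"c": "AAAACCCCTTTT"})
        assert frags(fm, "c") == [(0, 12)]

    def test_leading_cut_drops_zero_length_fragment(self):
        fm = h3c.digest_genome({"c": "GATCGATC"})
        assert frags(fm, "c") == [(0, 4), (4, 8)]

    def test_non_acgt_warns_and_never_matches(self):
        with pytest.warns(UserWarning):
            fm = h3c.digest_genome({"c": "AANNGATCNN"})
        assert frags(fm, "c") == [(0, 4), (4, 10)]

    def test_matches_naive_scan_and_tiles_random_sequences(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 2000))))
            fm = h3c.digest_genome({"c": seq})
            cuts = sorted({i for i in range(len(seq)) if seq[i : i + 4] == "GATC"} | {0, len(seq)})
            expected = [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1) if cuts[i + 1] > cuts[i]]
            got = frags(fm, "c")
            assert got == expected
            # tiling: contiguous, and concatenating fragments reproduces the genome
            assert got[0][0] == 0 and got[-1][1] == len(seq)
            assert all(a[1] == b[0] for a, b in zip(got, got[1:]))
            assert "".join(seq[s:e] for s, e in got) == seq
            # every fragment after the first starts with the site
            assert all(seq[s : s + 4] == "GATC" for s, _ in got[1:])

    def test_fragment_index_lookup(self):
        fm = h3c.digest_genome({"c": "AAGATCCCGATCAA"})
        assert [fm.fragment_index("c", p) for p in (0, 1, 2, 7, 8, 13)] == [0, 0, 1, 1, 2, 2]
        with pytest.raises(InputError):
            fm.fragment_index("c", 14)


BAIT_FRAG = "GATC" + "TTACGGTACCATGGAAACCA" + "CCTGTACGAA"  # primer inside
PARTNER = "GATC" + "ACGTACGTACGTACGTACGTAAAA"


def toy_setup():
    """Two-chromosome toy genome: bait fragment on c1, partner pool on c2."""
    c1 = "AACC" + BAIT_FRAG + "GATC" + "GGTTGGTTGGTTGGTTGGTTGGTT"
    c2 = PARTNER + "GATC" + "CCGGCCGGCCGGCCGGCCGGCCGG"
    genome = {"c1": c1, "c2": c2}
    fm = h3c.digest_genome(genome)
    bait = h3c.BaitSpec("c1", 1, "TTACGGTACCATGGAAACCA", adapter="")
    return genome, fm, bait


class TestPreprocess:
    def test_read_without_primer_dropped(self):
        _, _, bait = toy_setup()
        junctions, tallies = h3c.preprocess_reads([("r1", "ACGT" * 30)], bait)
        assert junctions == [] and tallies["no_primer"] == 1

    def test_constructed_read_yields_partner_at_junction(self):
        _, _, bait = toy_setup()
        read = "NN" + bait.nested_primer + "CCTGTACGAA" + PARTNER
        junctions, tallies = h3c.preprocess_reads([("r1", read)], bait)
        assert len(junctions) == 1
        jr = junctions[0]
        assert jr.partner_seq == PARTNER
        assert read[jr.junction_offset : jr.junction_offset + 4] == "GATC"
        assert tallies == {"no_primer": 0, "no_site": 0}

    def test_primer_without_junction_site_dropped(self):
        _, _, bait = toy_setup()
        junctions, tallies = h3c.preprocess_reads(
            [("r1", bait.nested_primer + "CCTTAACCTTAA")], bait
        )
        assert junctions == [] and tallies["no_site"] == 1

    def test_partner_stops_at_adapter(self):
        _, _, _ = toy_setup()
        bait = h3c.BaitSpec("c1", 1, "TTACGGTACCATGGAAACCA", adapter="CTGTCTCTTATACACATCT")
        read = bait.nested_primer + "CC" + "GATCAAAACCCC" + bait.adapter + "GGGG"
        junctions, _ = h3c.preprocess_reads([("r1", read)], bait)
        assert junctions[0].partner_seq == "GATCAAAACCCC"


class TestMapping:
    def test_verbatim_partner_maps_to_source_fragment(self):
        genome, fm, bait = toy_setup()
        jr = h3c.JunctionRead("r1", "x", PARTNER, 0)
        hits, tallies = h3c.map_partner_fragments([jr], genome, fm)
        assert hits == [(jr, ("c2", 0))]
        assert tallies["unmapped"] == 0

    def test_ambiguous_partner_unmapped(self):
        dup = "GATC" + "ACGTACGTACGTACGTTTTTTTTT"
        genome = {"c1": dup + dup, "c2": "A" * 30}
        fm = h3c.digest_genome(genome)
        jr = h3c.JunctionRead("r1", "x", dup, 0)
        hits, tallies = h3c.map_partner_fragments([jr], genome, fm)
        assert hits == [] and tallies["unmapped"] == 1

    def test_short_partner_unmapped(self):
        genome, fm, _ = toy_setup()
        jr = h3c.JunctionRead("r1", "x", "GATCAA", 0)
        hits, tallies = h3c.map_partner_fragments([jr], genome, fm)
        assert hits == [] and tallies["unmapped"] == 1

    def test_sam_mode_converts_primary_alignments(self, tmp_path):
        genome, fm, _ = toy_setup()
        jrs = [h3c.JunctionRead(f"r{i}", "x", PARTNER, 0) for i in range(2)]
        sam = tmp_path / "aln.sam"
        lengths = {c: len(s) for c, s in genome.items()}
        with open(sam, "w") as fh:
            for c, L in lengths.items():
                fh.write(f"@SQ\tSN:{c}\tLN:{L}\n")
            fh.write("r0\t0\tc2\t1\t60\t10M\t*\t0\t0\tGATCACGTAC\t*\n")
            fh.write("r1\t4\t*\t0\t0\t*\t*\t0\t0\tGATCACGTAC\t*\n")  # unmapped
        hits, tallies = h3c.map_partner_fragments(jrs, None, fm, mode="sam", sam_path=str(sam))
        assert [(jr.read_id, frag) for jr, frag in hits] == [("r0", ("c2", 0))]
        assert tallies["unmapped"] == 1

    def test_sam_with_unknown_reference_rejected(self, tmp_path):
        genome, fm, _ = toy_setup()
        sam = tmp_path / "aln.sam"
        sam.write_text("@SQ\tSN:chrX\tLN:100\n")
        with pytest.raises(InputError):
            h3c.map_partner_fragments([], None, fm, mode="sam", sam_path=str(sam))


def big_map(n=10):
    """Linear fragment map with n fragments of 100 bp on one chromosome."""
    seq = "".join("GATC" + "".join(np.random.default_rng(i).choice(list("ACGT"), 96)) for i in range(n))
    genome = {"c": seq}
    return genome, h3c.digest_genome(genome)


class TestFilterAndCount:
    def _hit(self, i, frag, seq=None):
        return (h3c.JunctionRead(f"r{i}", "p", seq or f"partner{i}", 0, seq or f"read{i}"), frag)

    def test_hand_tally_of_the_three_rules(self):
        genome, fm = big_map()
        bait = h3c.BaitSpec("c", 4, "A" * 20)
        hits = (
            [self._hit(i, ("c", 4)) for i in range(4)]  # self-ligation
            + [self._hit(4, ("c", 3)), self._hit(5, ("c", 5))]  # religation
            + [self._hit(6, ("c", 0), "dupread"), self._hit(7, ("c", 0), "dupread")]  # dup pair
            + [self._hit(8, ("c", 1)), self._hit(9, ("c", 7))]
        )
        profile = h3c.filter_and_count(hits, bait, fm)
        assert profile.tallies == {"self_ligation": 4, "religation": 2, "duplicate": 1}
        assert sum(profile.raw_counts.values()) == 3
        assert profile.raw_counts == {("c", 0): 1, ("c", 1): 1, ("c", 7): 1}

    def test_all_self_ligation_gives_empty_profile(self):
        genome, fm = big_map()
        bait = h3c.BaitSpec("c", 2, "A" * 20)
        with pytest.warns(UserWarning):
            profile = h3c.filter_and_count(
                [self._hit(i, ("c", 2)) for i in range(5)], bait, fm
            )
        assert profile.raw_counts == {} and profile.total_retained == 0
        assert all(v == 0.0 for v in profile.normalized.values())

    def test_normalization_to_1e5(self):
        genome, fm = big_map()
        bait = h3c.BaitSpec("c", 9, "A" * 20)
        hits = [self._hit(i, ("c", 3)) for i in range(10)]
        profile = h3c.filter_and_count(hits, bait, fm)
        assert profile.normalized[("c", 3)] == pytest.approx(1e5)

    def test_bedgraph_rows_and_round_trip(self, tmp_path):
        genome, fm = big_map()
        bait = h3c.BaitSpec("c", 9, "A" * 20)
        hits = [self._hit(i, ("c", i % 3)) for i in range(9)]
        profile = h3c.filter_and_count(hits, bait, fm)
        path = tmp_path / "p.bedGraph"
        h3c.write_profile_bedgraph(profile, str(path))
        df = io.read_bedgraph(str(path))
        assert len(df) == 3
        norm = profile.normalized
        for row in df.itertuples(index=False):
            idx = fm.fragment_index(row.chrom, row.start)
            assert row.value == pytest.approx(norm[(row.chrom, idx)], abs=1e-6)

    def test_empty_profile_writes_header_only(self, tmp_path):
        genome, fm = big_map()
        profile = h3c.InteractionProfile(fm, {}, {}, 0)
        path = tmp_path / "empty.bedGraph"
        h3c.write_profile_bedgraph(profile, str(path))
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("track")


class TestComparison:
    def _profile(self, fm, counts):
        return h3c.InteractionProfile(fm, counts, {}, sum(counts.values()))

    def test_identical_profiles_have_ratio_one(self):
        _, fm = big_map()
        counts = {("c", 0): 5, ("c", 3): 10}
        cmp_ = h3c.compare_profiles(
            self._profile(fm, counts), self._profile(fm, counts), ("c", 0, 1000), seed=0
        )
        assert cmp_.ratio == pytest.approx(1.0)
        assert cmp_.ci_low <= 1.0 <= cmp_.ci_high

    def test_zero_region_in_b_gives_ratio_zero(self):
        _, fm = big_map()
        a = self._profile(fm, {("c", 2): 5})
        b = self._profile(fm, {("c", 7): 5})
        cmp_ = h3c.compare_profiles(a, b, ("c", 200, 300), seed=0)
        assert cmp_.ratio == 0.0

    def test_region_outside_map_rejected(self):
        _, fm = big_map()
        p = self._profile(fm, {("c", 0): 1})
        with pytest.raises(InputError):
            h3c.compare_profiles(p, p, ("chrZ", 0, 100), seed=0)


class TestEndToEndSynthetic:
    def test_read_conservation_and_normalized_sum(self, genome, fragment_map, bait, sim_config):
        from seloopkit import synthetic_data as sd

        reads, _ = sd.simulate_3c_reads(genome, sim_config, "NC")
        profile = h3c.profile_from_reads(reads, genome.sequences, fragment_map, bait)
        total = sum(profile.raw_counts.values()) + sum(profile.tallies.values())
        assert total == len(reads)
        assert sum(profile.normalized.values()) == pytest.approx(1e5, rel=1e-9)

    def test_vast_majority_of_valid_reads_hit_true_fragment(self, genome, fragment_map, bait, sim_config):
        from seloopkit import synthetic_data as sd

        reads, truth = sd.simulate_3c_reads(genome, sim_config, "NC")
        junctions, _ = h3c.preprocess_reads(reads, bait)
        hits, tallies = h3c.map_partner_fragments(junctions, genome.sequences, fragment_map)
        n_valid = truth["se_partner"] + truth["bg_partner"] + truth["self_ligation"] + truth["religation"] + truth["duplicate"]
        assert len(hits) / n_valid >= 0.99
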