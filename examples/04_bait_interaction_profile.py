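"""Bait-anchored chromatin-interaction profiling under knockdown.

Digests the synthetic genome at every GATC (MboI), simulates bait-anchored
junction reads for a control (NC) and a cohesin-knockdown (KD) condition in
which super-enhancer contacts are halved, filters self-ligation/religation/
duplicate artifacts, normalizes to reads per 100,000, and compares the
SE-region signal between conditions.
"""

from seloopkit import htgts3c as h3c, synthetic_data as sd

config = sd.SimulationConfig(seed=1)  # kd_contact_ratio = 0.5
genome = sd.generate_genome(config)
frag_map = genome.fragment_map()
bait = sd.bait_spec_for(genome)
print(f"genome digested into {frag_map.n_fragments()} MboI fragments; "
      f"bait fragment {bait.chrom}:{genome.bait[1]}-{genome.bait[2]}")

profiles = {}
for condition in ("NC", "KD"):
    reads, _ = sd.simulate_3c_reads(genome, config, condition)
    profiles[condition] = h3c.profile_from_reads(reads, genome.sequences, frag_map, bait)
    t = profiles[condition].tallies
    print(f"{condition}: {len(reads)} reads -> {profiles[condition].total_retained} retained "
          f"(self-ligation {t['self_ligation']}, religation {t['religation']}, "
          f"duplicates {t['duplicate']})")

region = genome.truth_se_regions[0]
cmp_ = h3c.compare_profiles(
    profiles["NC"], profiles["KD"], (region.chrom, region.start, region.end), seed=1
)
print(f"SE region {region.chrom}:{region.start}-{region.end} (gene {region.gene_id}):")
print(f"  normalized signal NC {cmp_.sum_a:,.0f} vs KD {cmp_.sum_b:,.0f}")
print(f"  KD/NC ratio {cmp_.ratio:.2f} (95% bootstrap CI {cmp_.ci_low:.2f}-{cmp_.ci_high:.2f})")
# A ratio near 0.5 recovers the simulated halving of promoter-SE contacts.
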