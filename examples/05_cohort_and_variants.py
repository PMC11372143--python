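"""Clinical cohort frequencies and rare-variant prioritization.

Generates the curated CdLS cohort table (patient counts per mutated cohesin
gene), computes per-gene CHD frequencies and the outflow-tract fraction for
SMC3 carriers, then applies the coding and noncoding variant filters to a
planted annotation panel. Ends with the qPCR 2^-ddCt formula.
"""

from seloopkit import cohort_variants as cv, synthetic_data as sd

cohort, variants, truth = sd.simulate_cohort_and_variants(sd.SimulationConfig(seed=0))

freq = cv.chd_frequency_by_gene(cohort)
print("CHD frequency by mutated cohesin gene:")
for row in freq.itertuples(index=False):
    print(f"  {row.gene:6s} {row.n_chd:3d}/{row.n_total:3d}  {row.percent:6.2f}%")

n_oft, n_typed, pct = cv.oft_fraction(cohort, "SMC3")
print(f"SMC3 carriers with outflow-tract-type CHD: {n_oft}/{n_typed} = {pct}%")

coding = variants[variants["region_class"] == "coding"]
retained, tallies = cv.filter_coding_variants(coding)
print(f"\ncoding filter: {len(coding)} variants -> {len(retained)} retained "
      f"(excluded: {tallies['synonymous']} synonymous, {tallies['maf']} common, "
      f"{tallies['deleteriousness']} insufficiently damaging)")
noncoding = variants[variants["region_class"] != "coding"]
kept_nc = cv.filter_noncoding_variants(noncoding)
print(f"noncoding filter: {len(noncoding)} variants -> {len(kept_nc)} retained")

fold = cv.relative_expression_ddct(24.0, 18.0, 22.0, 18.0)
print(f"\nqPCR example: target Ct 24 vs 22 (reference 18 in both) -> "
      f"2^-ddCt = {fold:.2f}-fold (expression halved twice = {fold:.2f}x control)")
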