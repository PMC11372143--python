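# Methods

## Super-enhancer calling

Stitching merges two peaks exactly when the gap between them is ≤ the stitch
distance (default 12,500 bp, the canonical rank-ordering default; TSS
exclusion is off by default and, when supplied, removes peaks fully inside an
excluded window before stitching so they can neither seed nor bridge a
merge). Scores are Σ coverage × width over the stitched span from a bedGraph
signal track; when a control track is given the same sum is subtracted and
the result floored at 0, so a control-dominated region keeps its rank but can
never be called super. The cutoff on the min–max-scaled rank-signal curve is
the argmax of scaled_rank − scaled_signal; among tied maximizers the largest
index is taken (fewest super-enhancers, the conservative choice), and
`is_super` requires signal strictly greater than the cutoff signal so the
cutoff region itself is typical. Coordinates are 0-based half-open
throughout; BED input/output is unchanged.

Degenerate input — all scores equal — has no defined cutoff and raises an
error rather than guessing. Fewer than three regions likewise.

## SE-associated-gene screen

"Most closely related gene" is operationalized as the gene whose TSS is
nearest the SE midpoint, one gene per SE, deduplicated per gene keeping the
minimal distance; ties go to the lexicographically smaller gene id, and an SE
on a chromosome with no annotated gene is reported unassigned rather than
failing the run. The expression step keeps the top ⌊fraction · n⌋ candidates
by FPKM (truncation, because 0.2 × 1544 = 308.8 and the screen's reported
size is 308); boundary ties are broken by ascending gene id so the output
size is exact, and candidates missing from the FPKM table score 0 rather
than being dropped, keeping the candidate count stable. Which distance metric
and FPKM replicate the original screen used is not documented anywhere we
know of; nearest-TSS-to-midpoint is the assumption made here and the 1:1
SE→gene mapping follows from the screen's own 1544 → 1544 arithmetic.

## bimod differential expression

Expression is log1p-transformed; a cell "expresses" a gene when the
transformed value exceeds the expression threshold (default 0). The
likelihood is a two-part mixture: a Bernoulli for expression incidence and a
Normal for expressed values. The alternative fits (π_g, μ_g) per group with
one pooled σ estimated from the residuals about the group means; the null
shares (π, μ). Because σ is estimated once under the alternative and plugged
into both models, the statistic decomposes as a binomial LRT plus
(SSE_null − SSE_alt)/σ̂², is non-negative by construction, and is referred to
χ² with 2 degrees of freedom (the two parameters freed by the alternative).
Genes expressed in no cell of either group get p = 1; genes whose expressed
values are all identical but whose group means differ get a large capped
statistic (perfect separation). Empirically the test is mildly
anti-conservative at n = 100 cells/group (type-I ≈ 0.055 at α = 0.05), the
residue of the discrete binomial component.

The reported log2 fold change is log2((mean_B + 1)/(mean_A + 1)) with means
taken over all cells on the original scale — the standard single-cell fold
change, which responds to both dropout and expression-level shifts and
preserves a planted effect under 50% dropout (a mixture-mean-on-log-scale
definition would halve it). Down-gene selection applies fold change > 1.5
and p < 0.05 with strict inequalities; the same rule is used for the
single-nucleus screen as for bulk, an assumption since no separate
single-nucleus cutoff is documented. Gene symbols are case-normalized to
Title case before intersection so mouse-style and upper-case symbol
conventions meet.

## Bait-anchored interaction profiling

MboI digestion is modeled as a cut 5′ of every GATC occurrence, scanning
every position, so fragments tile each chromosome exactly and every fragment
after the first begins with GATC; overhang chemistry is ignored (no
computational consequence). Junction extraction keeps reads containing the
nested primer, finds the first GATC at or after the primer (the ligation
junction), and takes the partner side up to the next GATC or the adapter
start. "Self-ligation" is a hit to the bait fragment itself, "religation" a
hit to either bait-adjacent fragment, and a "duplicate" is a read-identical
molecule hitting the same fragment beyond its first occurrence — standard
4C-practice definitions. Artifact order matters: self/religation are removed
before deduplication, so an artifact read is tallied once under its artifact
class. Counts are normalized per 100,000 retained mapped reads (the scale is
a reporting choice; only ratios of normalized values are interpreted).

The default exact mapper assigns a partner by hash lookup of its first
20 bases against fragment-start-anchored 20-mers, requiring a unique hit —
sufficient for synthetic genomes and dependency-free; real alignments enter
through SAM ingestion of primary alignments instead. Mates are assumed merged
upstream; this module consumes single merged reads.

Region comparison reports the ratio of region-summed normalized signal
(condition B over A) with a seeded percentile bootstrap over the region's
fragments (1000 resamples). Note the normalization couples the ratio to the
library composition: if SE-region reads are a fraction r/(1+r) of retained
reads (r = enriched weight / background weight), the expected measured ratio
for a true contact reduction k is k·(1+r)/(1+kr), biased toward 1 by ≈
r(1−k) for small r. The synthetic defaults keep r ≈ 0.1 so the bias is a few
percent; analyses of real data with very strong bait-proximal enrichment
should interpret the raw ratio with the same caveat.

## Synthetic data

The generators define the conditions the pipeline is exercised under; every
stream derives from (seed, generator name), so runs are byte-reproducible
and adding a generator never perturbs the others.

- **Genome**: 2 chromosomes × 500 kb of uniform random sequence (GATC lands
  ~1 per 256 bp, ≈ 1950 MboI fragments per chromosome). Forty gene/enhancer
  units are laid out with inter-unit gaps above the stitch distance: a 2 kb
  gene, then a cluster of 2–4 constituent peaks (400–800 bp, gaps
  300–800 bp) a few kb downstream. 10% of clusters are designated
  super-enhancers; the planted SE region is the cluster's bounding interval
  and the paired gene is the planted SE gene. The bait is the MboI fragment
  containing the first gene's TSS (chosen with mappable neighbours so
  religation partners are assignable).
- **Signal**: typical constituents draw Gamma(2, 1.5)+0.5 heights; SE
  constituents draw a common cluster base 30·(1+Pareto(α)) with α = 3 —
  heavy-tailed enough for a convex hockey stick, light-tailed enough that no
  single SE dwarfs the min–max scaling and hides the others (α < 2 makes
  recovery of co-planted SEs unreliable, which is why the default is 3).
  Background bins carry Gamma(1, 0.2) noise.
- **Expression**: log-normal FPKM (μ=2, σ=1), SE genes multiplied by 10.
- **Counts**: 1000 genes × 2 × 100 cells; expression probability π = 0.5;
  expressed log-values Normal(μ_g, 1) truncated to (0, ∞) via inverse-CDF so
  the zero mass equals 1 − π exactly; planted DE genes (10%) shifted down by
  log2FC 2 in group B. 5% of cells violate QC (half with exactly 150
  detected genes, half with mitochondrial fraction ≥ 25%).
- **3C reads**: each read emulates a merged mate pair off a sonicated
  ligation concatemer — primer + 30 bp bait tail + partner fragment from its
  GATC, reading through into a further ligated fragment when the uniform
  sonication breakpoint lies beyond the partner, + adapter, truncated to
  300 nt. The variable breakpoint and read-through partner give independent
  molecules to the same fragment distinct sequences, so duplicate marking
  (read-identical molecules) almost exclusively catches the planted 5%
  duplicates; residual birthday collisions add ≈ 5–10% to the duplicate
  tally, which the truth-round-trip tests allow for. Self-ligation 30%,
  religation 10%. SE fragments carry 10-fold contact weight (a realistic 4C
  enrichment that also keeps the SE read share low enough for the ratio bias
  analysis above); under "KD" that weight is multiplied by
  kd_contact_ratio = 0.5. Sequencing error is not modeled.
- **Cohort/variants**: patient counts per cohesin gene are emitted exactly as
  configured (defaults encode the curated table: NIPBL 58/217, RAD21 11/43,
  SMC1A 14/58, HDAC8 8/49, SMC3 22/42 with 16/21 OFT-typed); the variant
  panel plants one pass and one fail case for every filter clause. The three
  screen gene lists are synthetic stand-ins at the reported sizes
  (4628/730/308) whose exact triple intersection is the four shared genes,
  with named members of each screen included and disjoint filler symbols.

What passing these tests shows — and does not. The generators reproduce the
structural features each stage keys on (convex rank–signal curves, zero
inflation, junction structure, artifact classes, planted effects), not read
mappability, GC or fragment-length biases, diploidy, doublets, batch
effects, or ambient contamination. Recovery rates on synthetic data are
therefore statements about the implementation's correctness under its model
assumptions, not performance claims about any real library.

## Problem sizes and numerics

Default test/acceptance sizes: 1 Mb genome, 40 clusters, 20,000 3C reads per
condition, 2000 null genes and 200 cells for DE calibration — each stage
runs in seconds. Bootstrap CIs use 1000 resamples. Percent values round
half-up at the reported precision (decimal arithmetic, not banker's
rounding). Checksums are SHA-256 of output files; manifests exclude wall
time from comparisons. Scores and normalized counts are double precision;
the only tolerance-sensitive check is Σ normalized = 100,000, held to
floating round-off.

## Known limitations

- The exact mapper requires ≥ 20 bp unique fragment prefixes; fragments
  shorter than 20 bp are unmappable (rare at GATC density; real data should
  use SAM ingestion).
- The bimod χ²(2) reference is asymptotic; at very small groups the test is
  anti-conservative.
- The screen's nearest-gene definition and the single-nucleus down-gene
  cutoffs are assumptions (documented above); alternative definitions would
  change candidate lists on real data.
- Venn region counts are exact but reported by membership mask, not plotted.
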