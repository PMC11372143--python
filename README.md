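# seloopkit

Tools for the computational chain used to study how the cohesin subunit SMC3
regulates super-enhancer-associated heart-development genes: super-enhancer
calling from H3K27ac signal, the SE-associated-gene expression screen,
zero-inflated single-nucleus differential expression with gene-set
intersection, bait-anchored chromatin-interaction profiling (3C-HTGTS /
4C-style restriction-fragment counting), and clinical cohort / rare-variant
prioritization arithmetic. A synthetic-data module generates every input with
planted ground truth, so the whole pipeline is testable offline.

It is written for regulatory-genomics analysts who want each of these stages
as a small, tested, importable function rather than a monolithic script.

## The methods in brief

**Super-enhancer calling (ROSE-style).** Constituent H3K27ac peaks within a
stitch distance *d* (default 12,500 bp) are merged; each stitched region is
scored by Σ coverage × width over its span (optionally control-subtracted,
floored at 0). Regions are sorted ascending by signal, rank index and signal
are each min–max scaled to [0, 1], and the cutoff is the index maximizing
scaled_rank − scaled_signal — the point where the tangent to the convex
"hockey stick" has slope 1. Regions with signal strictly above the cutoff
signal are super-enhancers.

**SE-gene screen.** Each super-enhancer is assigned the gene whose TSS is
nearest its midpoint; the top ⌊0.2 · n⌋ candidates by FPKM are kept
(1544 candidates → 308 genes).

**bimod differential expression.** Per gene, log1p expression is a mixture:
zero with probability 1 − π, else Normal(μ, σ²). The alternative allows
group-specific (π_g, μ_g) with pooled σ; the statistic is twice the
log-likelihood gap, referred to χ² with 2 df. Down-regulated genes are
selected at fold change > 1.5 and p < 0.05 (both strict), and gene sets are
intersected after case-normalizing symbols.

**Bait-anchored interaction profiling.** The genome is digested 5′ of every
GATC (MboI). Reads carrying the nested bait primer are split at the first
GATC after the bait portion; the following restriction fragment is the
partner. Self-ligation (bait fragment), religation (the two bait-adjacent
fragments) and duplicate reads are removed; retained counts per fragment are
normalized to reads per 100,000 and compared between conditions per region.

**Cohort / variant arithmetic.** Per-gene CHD frequencies and the
outflow-tract-type fraction with half-up rounding; the coding filter
(non-synonymous, max MAF across GnomAD/ExAC < 0.1%, nonsense/frameshift or
≥ 2 damaging algorithm calls among SIFT "D", PolyPhen2 "P"/"D",
CADD phred > 20); the noncoding filter (MAF < 0.1% plus a regulatory /
splice / microRNA-binding annotation); and qPCR 2^−ΔΔCt.

## Worked example

```bash
python examples/04_bait_interaction_profile.py
```

prints

```
genome digested into 3946 MboI fragments; bait fragment chr1:4417-5361
NC: 20000 reads -> 11281 retained (self-ligation 5723, religation 1928, duplicates 1065)
KD: 20000 reads -> 11301 retained (self-ligation 5715, religation 1952, duplicates 1022)
SE region chr1:266038-268867 (gene gene011):
  normalized signal NC 3,209 vs KD 1,495
  KD/NC ratio 0.47 (95% bootstrap CI 0.39-0.56)
```

The simulation halves super-enhancer contacts in the knockdown (KD)
condition; after artifact filtering and per-100,000 normalization the
SE-region signal ratio recovers that 0.5 within the bootstrap CI. The other
examples (`examples/01…05`) walk through SE calling, the 1544 → 308 screen,
single-nucleus DE with the three-way gene-list intersection, and the cohort
and variant filters.

The same stages run from a shell via the `seloopkit` CLI
(`seloopkit sim`, `seloopkit se`, `seloopkit genes`, `seloopkit intersect`,
`seloopkit freq`, `seloopkit variants`, `seloopkit run --config run.yaml`),
with a manifest of outputs and checksums written per run.

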