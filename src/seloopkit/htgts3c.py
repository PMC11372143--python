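"""Bait-anchored chromatin-interaction profiling (3C-HTGTS / 4C style).

The genome is digested in silico at every GATC occurrence (MboI; the cut is
modeled 5' of the site so every fragment after the first begins with GATC).
Reads anchored at a bait restriction fragment are scanned for the nested
primer; the first GATC after the bait portion marks the ligation junction and
the following restriction fragment is the interaction partner. Partner hits
are filtered for self-ligation (the bait fragment), religation (the two
bait-adjacent fragments), and duplicates, then counted per fragment and
normalized to reads per 100,000 retained mapped reads.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from . import io

logger = logging.getLogger(__name__)

NORMALIZATION_SCALE = 100_000.0
DEFAULT_SITE = "GATC"
EXACT_MAP_K = 20


@dataclass
class RestrictionFragmentMap:
    """Ordered half-open restriction fragments per chromosome.

    Fragments tile each chromosome exactly: disjoint, contiguous, covering
    [0, len). A fragment is addressed by (chrom, index).
    """

    fragments: dict[str, np.ndarray]  # chrom -> array of boundaries, shape (n+1,)
    enzyme: str = "MboI"
    site: str = DEFAULT_SITE

    def n_fragments(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.fragments[chrom]) - 1
        return sum(len(b) - 1 for b in self.fragments.values())

    def fragment(self, chrom: str, index: int) -> tuple[int, int]:
        b = self.fragments[chrom]
        if not (0 <= index < len(b) - 1):
            raise InputError(f"fragment index {index} out of range for {chrom}")
        return int(b[index]), int(b[index + 1])

    def fragment_index(self, chrom: str, pos: int) -> int:
        """Index of the fragment containing base ``pos``."""
        b = self.fragments[chrom]
        if not (b[0] <= pos < b[-1]):
            raise InputError(f"position {chrom}:{pos} outside digested chromosome")
        return int(np.searchsorted(b, pos, side="right") - 1)

    def iter_fragments(self):
        for chrom, b in self.fragments.items():
            for i in range(len(b) - 1):
                yield chrom, i, int(b[i]), int(b[i + 1])

    def overlapping(self, chrom: str, start: int, end: int) -> list[int]:
        """Indices of fragments overlapping [start, end)."""
        if chrom not in self.fragments:
            return []
        b = self.fragments[chrom]
        lo = max(int(np.searchsorted(b, start, side="right") - 1), 0)
        hi = int(np.searchsorted(b, end, side="left"))
        return [i for i in range(lo, min(hi, len(b) - 1)) if b[i + 1] > start and b[i] < end]


@dataclass(frozen=True)
class BaitSpec:
    """The anchor fragment plus the primer/adapter sequences used to build and
    parse junction reads."""

    chrom: str
    fragment_index: int
    nested_primer: str
    adapter: str = ""

    def __post_init__(self):
        if len(self.nested_primer) < 15:
            raise InputError("nested primer must be >= 15 nt")


@dataclass(frozen=True)
class JunctionRead:
    read_id: str
    bait_prefix: str  # primer through the junction
    partner_seq: str  # first restriction fragment after the junction (GATC-leading)
    junction_offset: int
    read_seq: str = ""  # full read; duplicates are read-identical molecules


@dataclass
class InteractionProfile:
    """Per-fragment raw and normalized counts plus artifact-filter tallies."""

    fragment_map: RestrictionFragmentMap
    raw_counts: dict[tuple[str, int], int]
    tallies: dict[str, int]
    total_retained: int

    @property
    def normalized(self) -> dict[tuple[str, int], float]:
        if self.total_retained == 0:
            return {k: 0.0 for k in self.raw_counts}
        return {
            k: v / self.total_retained * NORMALIZATION_SCALE
            for k, v in self.raw_counts.items()
        }

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        frags = self.fragment_map.overlapping(chrom, start, end)
        norm = self.normalized
        return sum(norm.get((chrom, i), 0.0) for i in frags)


def digest_genome(sequences: dict[str, str], site: str = DEFAULT_SITE) -> RestrictionFragmentMap:
    """Cut 5' of every occurrence of ``site`` (scanning every position, so
    overlapping occurrences each cut); zero-length fragments are dropped."""
    if not site:
        raise InputError("restriction site must be non-empty")
    fragments = {}
    for chrom, seq in sequences.items():
        seq = seq.upper()
        if set(seq) - set("ACGT"):
            warnings.warn(f"{chrom}: non-ACGT characters present; they never match the site")
        cuts = []
        i = seq.find(site)
        while i != -1:
            cuts.append(i)
            i = seq.find(site, i + 1)
        boundaries = [0] + cuts + [len(seq)]
        boundaries = sorted(set(boundaries))
        # drop zero-length (cut at position 0 duplicates the left end)
        fragments[chrom] = np.asarray(boundaries, dtype=np.int64)
        if len(seq) == 0:
            raise InputError(f"{chrom}: empty sequence")
    return RestrictionFragmentMap(fragments=fragments, site=site)


def preprocess_reads(
    reads: Iterable[tuple[str, str]], bait: BaitSpec, site: str = DEFAULT_SITE
) -> tuple[list[JunctionRead], dict[str, int]]:
    """Extract the first partner restriction fragment from each primer-bearing read.

    A read is kept when it contains the nested primer and a restriction site at
    or after the primer (the ligation junction); the partner side runs from
    that site to the next site or the adapter start, whichever comes first.
    Reads lacking the primer or any junction site are tallied and dropped.
    """
    tallies = {"no_primer": 0, "no_site": 0}
    out: list[JunctionRead] = []
    primer = bait.nested_primer.upper()
    adapter = bait.adapter.upper()
    n = 0
    for read_id, seq in reads:
        n += 1
        seq = seq.upper()
        i = seq.find(primer)
        if i == -1:
            tallies["no_primer"] += 1
            continue
        j = seq.find(site, i + len(primer))
        if j == -1:
            tallies["no_site"] += 1
            continue
        end = seq.find(site, j + len(site))
        if adapter:
            a = seq.find(adapter, j + len(site))
            if a != -1 and (end == -1 or a < end):
                end = a
        if end == -1:
            end = len(seq)
        out.append(JunctionRead(read_id, seq[i:j], seq[j:end], j, seq))
    if n == 0:
        warnings.warn("empty read set")
    return out, tallies


def build_exact_index(
    genome: dict[str, str], fragment_map: RestrictionFragmentMap, k: int = EXACT_MAP_K
) -> dict[str, list[tuple[str, int]]]:
    """Index fragment-start-anchored k-mers for exact partner lookup."""
    index: dict[str, list[tuple[str, int]]] = {}
    for chrom, i, start, end in fragment_map.iter_fragments():
        if end - start < k:
            continue
        key = genome[chrom][start : start + k].upper()
        index.setdefault(key, []).append((chrom, i))
    return index


def map_partner_fragments(
    junctions: Sequence[JunctionRead],
    genome: dict[str, str] | None,
    fragment_map: RestrictionFragmentMap,
    mode: str = "exact",
    sam_path: str | None = None,
    k: int = EXACT_MAP_K,
) -> tuple[list[tuple[JunctionRead, tuple[str, int]]], dict[str, int]]:
    """Assign each junction's partner sequence to a restriction fragment.

    exact mode: the partner's first k bases must match exactly one
    fragment-start-anchored k-mer of the genome; multi-hits and misses are
    tallied unmapped. sam mode: primary alignments from ``sam_path`` are
    converted to the containing fragment index.
    """
    tallies = {"unmapped": 0}
    hits: list[tuple[JunctionRead, tuple[str, int]]] = []
    if mode == "exact":
        if genome is None:
            raise InputError("exact mode requires the genome sequences")
        index = build_exact_index(genome, fragment_map, k=k)
        for jr in junctions:
            if len(jr.partner_seq) < k:
                tallies["unmapped"] += 1
                continue
            cand = index.get(jr.partner_seq[:k], [])
            if len(cand) != 1:
                tallies["unmapped"] += 1
                continue
            hits.append((jr, cand[0]))
    elif mode == "sam":
        import pysam

        if sam_path is None:
            raise InputError("sam mode requires sam_path")
        by_id = {jr.read_id: jr for jr in junctions}
        with pysam.AlignmentFile(sam_path, "r") as sam:
            refs = set(sam.references or ())
            missing = refs - set(fragment_map.fragments)
            if missing:
                raise InputError(f"SAM references absent from fragment map: {sorted(missing)}")
            seen = set()
            for aln in sam:
                if aln.is_secondary or aln.is_supplementary:
                    continue
                jr = by_id.get(aln.query_name)
                if jr is None or aln.query_name in seen:
                    continue
                seen.add(aln.query_name)
                if aln.is_unmapped:
                    tallies["unmapped"] += 1
                    continue
                frag = fragment_map.fragment_index(aln.reference_name, aln.reference_start)
                hits.append((jr, (aln.reference_name, frag)))
            tallies["unmapped"] += len(by_id) - len(seen)
    else:
        raise InputError(f"unknown mapping mode {mode!r}")
    return hits, tallies


def filter_and_count(
    hits: Sequence[tuple[JunctionRead, tuple[str, int]]],
    bait: BaitSpec,
    fragment_map: RestrictionFragmentMap,
    extra_tallies: dict[str, int] | None = None,
) -> InteractionProfile:
    """Remove self-ligation (bait fragment), religation (the two bait-adjacent
    fragments) and duplicate junctions, then count per fragment and normalize
    per 100,000 retained mapped reads."""
    if bait.chrom not in fragment_map.fragments:
        raise InputError(f"bait chromosome {bait.chrom!r} absent from fragment map")
    nb = fragment_map.n_fragments(bait.chrom)
    if not (0 <= bait.fragment_index < nb):
        raise InputError("bait fragment index outside fragment map")
    bait_key = (bait.chrom, bait.fragment_index)
    adjacent = {
        (bait.chrom, bait.fragment_index - 1),
        (bait.chrom, bait.fragment_index + 1),
    }
    tallies = {"self_ligation": 0, "religation": 0, "duplicate": 0}
    if extra_tallies:
        tallies.update(extra_tallies)
    counts: dict[tuple[str, int], int] = {}
    seen: set[tuple[str, str, int]] = set()
    for jr, frag in hits:
        if frag == bait_key:
            tallies["self_ligation"] += 1
            continue
        if frag in adjacent:
            tallies["religation"] += 1
            continue
        molecule = jr.read_seq or (jr.bait_prefix + jr.partner_seq)
        key = (molecule, frag[0], frag[1])
        if key in seen:
            tallies["duplicate"] += 1
            continue
        seen.add(key)
        counts[frag] = counts.get(frag, 0) + 1
    total = sum(counts.values())
    if total == 0:
        warnings.warn("no reads retained after artifact filtering; profile is empty")
    return InteractionProfile(
        fragment_map=fragment_map, raw_counts=counts, tallies=tallies, total_retained=total
    )


def profile_from_reads(
    reads: Iterable[tuple[str, str]],
    genome: dict[str, str],
    fragment_map: RestrictionFragmentMap,
    bait: BaitSpec,
    mode: str = "exact",
    sam_path: str | None = None,
) -> InteractionProfile:
    """Full chain: junction extraction -> fragment assignment -> artifact
    filtering/counting, with all tallies merged so every input read lands in
    exactly one tally or the retained counts."""
    junctions, pre_tallies = preprocess_reads(reads, bait, site=fragment_map.site)
    hits, map_tallies = map_partner_fragments(
        junctions, genome, fragment_map, mode=mode, sam_path=sam_path
    )
    return filter_and_count(
        hits, bait, fragment_map, extra_tallies={**pre_tallies, **map_tallies}
    )


def profile_to_frame(profile: InteractionProfile) -> pd.DataFrame:
    rows = []
    norm = profile.normalized
    for (chrom, idx), raw in sorted(profile.raw_counts.items()):
        start, end = profile.fragment_map.fragment(chrom, idx)
        rows.append((chrom, start, end, idx, raw, norm[(chrom, idx)]))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "fragment_index", "raw", "normalized"]
    )


def write_profile_bedgraph(profile: InteractionProfile, path: str) -> None:
    """One bedGraph row per fragment with a nonzero normalized count."""
    df = profile_to_frame(profile)
    df = df[df["normalized"] > 0]
    out = df[["chrom", "start", "end", "normalized"]].rename(columns={"normalized": "value"})
    io.write_bedgraph(out, path, track_name="3c_profile")


@dataclass
class RegionComparison:
    region: tuple[str, int, int]
    sum_a: float
    sum_b: float
    ratio: float
    ci_low: float
    ci_high: float
    n_fragments: int


def compare_profiles(
    profile_a: InteractionProfile,
    profile_b: InteractionProfile,
    region: tuple[str, int, int],
    n_boot: int = 1000,
    seed: int = 0,
) -> RegionComparison:
    """Ratio (b/a) of region-summed normalized signal, with a bootstrap CI over
    the fragments in the region (percentile, seeded)."""
    chrom, start, end = region
    if profile_a.fragment_map is not profile_b.fragment_map and (
        {c: tuple(b) for c, b in profile_a.fragment_map.fragments.items()}
        != {c: tuple(b) for c, b in profile_b.fragment_map.fragments.items()}
    ):
        raise InputError("profiles are on different fragment maps")
    frags = profile_a.fragment_map.overlapping(chrom, start, end)
    if not frags:
        raise InputError(f"region {chrom}:{start}-{end} overlaps no fragments")
    norm_a = profile_a.normalized
    norm_b = profile_b.normalized
    va = np.array([norm_a.get((chrom, i), 0.0) for i in frags])
    vb = np.array([norm_b.get((chrom, i), 0.0) for i in frags])
    sum_a, sum_b = float(va.sum()), float(vb.sum())
    ratio = sum_b / sum_a if sum_a > 0 else (0.0 if sum_b == 0 else float("inf"))
    rng = np.random.default_rng(seed)
    boots = []
    m = len(frags)
    for _ in range(n_boot):
        idx = rng.integers(0, m, size=m)
        sa, sb = va[idx].sum(), vb[idx].sum()
        if sa > 0:
            boots.append(sb / sa)
    if boots:
        ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    else:
        ci_low = ci_high = float("nan")
    return RegionComparison(region, sum_a, sum_b, ratio, float(ci_low), float(ci_high), m)
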