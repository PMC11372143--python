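"""Super-enhancer identification by rank ordering (ROSE-style).

Constituent H3K27ac peaks are stitched when the gap between them is at most a
stitch distance (default 12,500 bp), stitched regions are scored by summed
signal-track coverage over their span (optionally control-subtracted, floored
at zero), and the typical/super split is placed at the tangent-slope-1 point of
the min-max-scaled rank-versus-signal "hockey stick": after scaling both the
ascending rank index and the signal to [0, 1], the cutoff is the index that
maximizes scaled_rank - scaled_signal. Regions with signal strictly above the
signal at the cutoff index are super-enhancers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InputError
from . import io

logger = logging.getLogger(__name__)

DEFAULT_STITCH_DISTANCE = 12_500


@dataclass(frozen=True)
class EnhancerPeak:
    """A constituent enhancer peak (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    peak_id: str = ""

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise InputError(
                f"peak {self.peak_id!r}: invalid interval [{self.start}, {self.end})"
            )


class SignalTrack:
    """Per-chromosome sorted, non-overlapping coverage intervals.

    Stored as parallel numpy arrays per chromosome so interval sums are a pair
    of ``searchsorted`` calls. Values must be non-negative; uncovered bases
    contribute zero.
    """

    def __init__(self, intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._data = {}
        for chrom, (starts, ends, values) in intervals.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(values < 0):
                raise InputError(f"signal track {chrom}: negative coverage value")
            if np.any(ends <= starts):
                raise InputError(f"signal track {chrom}: empty or inverted interval")
            if np.any(starts[1:] < ends[:-1]):
                raise InputError(f"signal track {chrom}: overlapping intervals")
            self._data[chrom] = (starts, ends, values)

    @classmethod
    def from_bedgraph(cls, path: str) -> "SignalTrack":
        df = io.read_bedgraph(path)
        return cls.from_dataframe(df)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SignalTrack":
        grouped = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            grouped[chrom] = (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub["value"].to_numpy(),
            )
        return cls(grouped)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._data)

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of coverage x overlap-width over [start, end)."""
        if chrom not in self._data:
            return 0.0
        starts, ends, values = self._data[chrom]
        # intervals with end > start of query and start < end of query
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if lo >= hi:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return float(np.sum(ov * values[lo:hi]))


@dataclass
class StitchedEnhancer:
    """A stitched enhancer region with its constituent peaks."""

    chrom: str
    start: int
    end: int
    peak_ids: tuple[str, ...] = ()
    aggregate_signal: float | None = None


@dataclass
class SECall:
    """A ranked stitched enhancer with its super-enhancer verdict."""

    enhancer: StitchedEnhancer
    rank: int  # 1 = highest signal
    scaled_rank: float
    scaled_signal: float
    is_super: bool
    cutoff_signal: float


def stitch_peaks(
    peaks: list[EnhancerPeak],
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    tss_exclusion: list[tuple[str, int, int]] | None = None,
) -> list[StitchedEnhancer]:
    """Merge peaks whose gap is <= ``stitch_distance`` into stitched enhancers.

    Peaks lying fully inside any TSS-exclusion window are removed up front so
    they can neither seed nor bridge a merge. Output is disjoint and sorted.
    """
    if stitch_distance < 0:
        raise InputError("stitch_distance must be >= 0")
    if tss_exclusion:
        def excluded(p: EnhancerPeak) -> bool:
            return any(
                p.chrom == c and p.start >= s and p.end <= e
                for c, s, e in tss_exclusion
            )

        peaks = [p for p in peaks if not excluded(p)]
    out: list[StitchedEnhancer] = []
    for p in sorted(peaks, key=lambda p: (p.chrom, p.start, p.end)):
        if out and out[-1].chrom == p.chrom and p.start - out[-1].end <= stitch_distance:
            cur = out[-1]
            cur.end = max(cur.end, p.end)
            cur.peak_ids = cur.peak_ids + (p.peak_id,)
        else:
            out.append(StitchedEnhancer(p.chrom, p.start, p.end, (p.peak_id,)))
    return out


def score_stitched(
    stitched: list[StitchedEnhancer],
    signal: SignalTrack,
    control: SignalTrack | None = None,
) -> list[StitchedEnhancer]:
    """Score each stitched region: sum(coverage x width) over the span,
    minus the same sum on the control track when given, floored at 0."""
    scored = []
    missing: set[str] = set()
    for region in stitched:
        if region.chrom not in signal.chromosomes and region.chrom not in missing:
            missing.add(region.chrom)
            warnings.warn(
                f"chromosome {region.chrom!r} absent from signal track; scoring 0"
            )
        value = signal.interval_sum(region.chrom, region.start, region.end)
        if control is not None:
            value -= control.interval_sum(region.chrom, region.start, region.end)
        scored.append(replace(region, aggregate_signal=max(value, 0.0)))
    return scored


def call_super_enhancers(scored: list[StitchedEnhancer]) -> list[SECall]:
    """Split typical from super enhancers at the hockey-stick tangent point.

    Regions are sorted ascending by aggregate signal; the ascending rank index
    and the signal are each min-max scaled to [0, 1]; the cutoff index is the
    maximizer of scaled_rank - scaled_signal (ties broken toward the largest
    index, i.e. the fewest super-enhancers); ``is_super`` holds strictly above
    the cutoff signal, so the cutoff region itself is typical.
    """
    n = len(scored)
    if n < 3:
        raise InputError(f"need >= 3 scored regions, got {n}")
    signals = np.array([r.aggregate_signal for r in scored], dtype=float)
    if np.any(np.isnan(signals)):
        raise InputError("aggregate_signal missing; run score_stitched first")
    smin, smax = signals.min(), signals.max()
    if smax == smin:
        raise DegenerateInputError("all aggregate signals equal; no cutoff defined")
    # ascending sort; stable with genomic tie-break for determinism
    order = sorted(
        range(n), key=lambda i: (signals[i], scored[i].chrom, scored[i].start)
    )
    s_sorted = signals[order]
    scaled_rank = np.arange(n, dtype=float) / (n - 1)
    scaled_signal = (s_sorted - smin) / (smax - smin)
    diff = scaled_rank - scaled_signal
    cutoff_idx = int(np.flatnonzero(diff == diff.max()).max())
    cutoff_signal = float(s_sorted[cutoff_idx])
    calls = []
    for asc_idx, orig in enumerate(order):
        calls.append(
            SECall(
                enhancer=scored[orig],
                rank=n - asc_idx,
                scaled_rank=float(scaled_rank[asc_idx]),
                scaled_signal=float(scaled_signal[asc_idx]),
                is_super=bool(s_sorted[asc_idx] > cutoff_signal),
                cutoff_signal=cutoff_signal,
            )
        )
    calls.sort(key=lambda c: c.rank)
    return calls


def calls_to_frame(calls: list[SECall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.enhancer.chrom for c in calls],
            "start": [c.enhancer.start for c in calls],
            "end": [c.enhancer.end for c in calls],
            "rank": [c.rank for c in calls],
            "aggregate_signal": [c.enhancer.aggregate_signal for c in calls],
            "scaled_rank": [c.scaled_rank for c in calls],
            "scaled_signal": [c.scaled_signal for c in calls],
            "is_super": [c.is_super for c in calls],
            "cutoff_signal": [c.cutoff_signal for c in calls],
            "n_constituents": [len(c.enhancer.peak_ids) for c in calls],
        }
    )


def write_se_outputs(calls: list[SECall], bed_path: str, tsv_path: str) -> None:
    """BED of super-enhancer spans only; TSV of the full ranked table."""
    if not calls:
        raise InputError("no calls to write")
    table = calls_to_frame(calls)
    supers = table[table["is_super"]].copy()
    supers["name"] = [f"SE_{r}" for r in supers["rank"]]
    io.write_bed(supers[["chrom", "start", "end", "name"]], bed_path)
    io.write_tsv(table, tsv_path)


def read_se_table(tsv_path: str) -> pd.DataFrame:
    return io.read_tsv(tsv_path)
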