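"""Two-step super-enhancer-associated-gene screen and interval utilities.

Step 1 assigns each super-enhancer the gene whose TSS is nearest the SE
midpoint ("most closely related" gene). Step 2 keeps the top fraction (default
20%) of the candidate genes by FPKM, with truncation so 1544 candidates yield
exactly 308 selected genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    start: int
    end: int

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise InputError(f"gene {self.gene_id}: strand must be + or -")
        if not (self.start <= self.tss <= self.end):
            raise InputError(f"gene {self.gene_id}: TSS {self.tss} outside span")


@dataclass
class SEGeneScreenResult:
    """Outcome of the two-step screen."""

    candidates: pd.DataFrame  # gene_id, se_id, distance, fpkm
    selected: pd.DataFrame  # subset passing the expression filter
    fraction_used: float
    fpkm_source: str = ""

    @property
    def selected_genes(self) -> list[str]:
        return list(self.selected["gene_id"])


def gene_models_from_frame(df: pd.DataFrame) -> list[GeneModel]:
    return [
        GeneModel(r.gene_id, r.chrom, r.strand, int(r.tss), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def assign_nearest_gene(
    se_regions: pd.DataFrame, gene_models: list[GeneModel]
) -> tuple[pd.DataFrame, list[str]]:
    """Assign each SE region the gene with the TSS nearest its midpoint.

    ``se_regions`` needs columns chrom/start/end and optionally ``se_id``.
    Nearness is measured from the TSS to the SE midpoint; ties go to the
    lexicographically smaller gene_id. The reported distance is 0 when the TSS
    lies inside the SE span, otherwise the distance from the TSS to the nearer
    span edge. The candidate list is deduplicated per gene keeping the minimal
    distance. Returns (candidates frame, list of unassigned se_ids).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)

    rows = []
    unassigned = []
    for idx, se in enumerate(se_regions.itertuples(index=False)):
        se_id = getattr(se, "se_id", None) or f"SE_{idx + 1}"
        genes = by_chrom.get(se.chrom)
        if not genes:
            unassigned.append(se_id)
            continue
        mid = (se.start + se.end) / 2
        best = min(genes, key=lambda g: (abs(g.tss - mid), g.gene_id))
        if se.start <= best.tss < se.end:
            distance = 0
        else:
            distance = int(min(abs(best.tss - se.start), abs(best.tss - (se.end - 1))))
        rows.append((best.gene_id, se_id, distance))
    if unassigned:
        logger.warning("%d SE regions had no gene on their chromosome", len(unassigned))
    df = pd.DataFrame(rows, columns=["gene_id", "se_id", "distance"])
    if not df.empty:
        df = (
            df.sort_values(["gene_id", "distance", "se_id"])
            .drop_duplicates("gene_id", keep="first")
            .reset_index(drop=True)
        )
    return df, unassigned


def expression_filter(
    candidates: pd.DataFrame,
    fpkm_table: pd.DataFrame,
    fraction: float = 0.2,
    fpkm_source: str = "",
) -> SEGeneScreenResult:
    """Keep the top floor(fraction x n) candidate genes by FPKM.

    ``fpkm_table`` needs columns gene_id and fpkm. Candidates missing from the
    table are scored FPKM 0 (and logged) so the candidate count is stable.
    Boundary ties are broken by ascending gene_id so the output size is exact.
    """
    if not (0 < fraction <= 1):
        raise InputError(f"fraction must be in (0, 1], got {fraction}")
    fpkm = dict(zip(fpkm_table["gene_id"], fpkm_table["fpkm"]))
    cand = candidates.copy()
    missing = [g for g in cand["gene_id"] if g not in fpkm]
    if missing:
        logger.warning("%d candidate genes missing from FPKM table; scored 0", len(missing))
    cand["fpkm"] = [float(fpkm.get(g, 0.0)) for g in cand["gene_id"]]
    k = math.floor(fraction * len(cand))
    ranked = cand.sort_values(
        ["fpkm", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    selected = ranked.iloc[:k].reset_index(drop=True)
    return SEGeneScreenResult(
        candidates=ranked, selected=selected, fraction_used=fraction, fpkm_source=fpkm_source
    )


def interval_span_kb(start: int, end: int, one_based_inclusive: bool = False) -> int:
    """Span of an interval in whole kilobases (truncated).

    With ``one_based_inclusive`` the endpoints are counted inclusively, as in
    genome-browser coordinates; otherwise the interval is half-open.
    """
    if end < start:
        raise InputError(f"end {end} < start {start}")
    span = end - start + (1 if one_based_inclusive else 0)
    return span // 1000
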