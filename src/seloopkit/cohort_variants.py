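"""Clinical-cohort frequency arithmetic, rare-variant prioritization filters,
and the qPCR relative-quantification formula.

The cohort table holds curated CdLS patients (one row per patient: mutated
cohesin gene, CHD status, optional CHD-type label, and whether that type is an
outflow-tract category such as aorta / pulmonary-artery dysplasia). Variant
prioritization follows the three-step coding rule — drop synonymous variants,
require minor allele frequency below 0.1% across reference databases, and
require nonsense/frameshift consequence or missense predicted deleterious by
at least two algorithms (SIFT call "D", PolyPhen2 "P"/"D", CADD phred > 20) —
and the noncoding rule (MAF < 0.1% plus a regulatory, splice-site, or
microRNA-binding effect annotation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ["patient_id", "gene", "chd_status", "chd_type", "oft_type"]
MAF_COLUMNS = ["maf_gnomad", "maf_exac"]
LOF_CONSEQUENCES = {"nonsense", "frameshift"}


def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding at the reported precision (so 52.375 -> 52.38)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds of the coding-variant prioritization rule."""

    maf_max: float = 0.001
    min_deleterious_algorithms: int = 2
    cadd_min: float = 20.0

    def __post_init__(self):
        if not (0 < self.maf_max < 1):
            raise InputError(f"maf_max must be in (0, 1), got {self.maf_max}")
        if self.min_deleterious_algorithms < 1:
            raise InputError("min_deleterious_algorithms must be >= 1")


def chd_frequency_by_gene(cohort: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Per-gene CHD frequency: n_chd / n_total as a half-up-rounded percent.

    Returns one row per gene with >= 1 patient, sorted by descending percent;
    ``fraction`` carries the unrounded value.
    """
    if cohort.empty:
        raise InputError("cohort table is empty")
    rows = []
    for gene, sub in cohort.groupby("gene", sort=True):
        n_total = len(sub)
        n_chd = int(sub["chd_status"].astype(bool).sum())
        frac = n_chd / n_total
        rows.append((gene, n_chd, n_total, frac, round_half_up(100 * frac, decimals)))
    out = pd.DataFrame(rows, columns=["gene", "n_chd", "n_total", "fraction", "percent"])
    return out.sort_values("percent", ascending=False).reset_index(drop=True)


def oft_fraction(cohort: pd.DataFrame, gene: str, decimals: int = 1) -> tuple[int, int, float]:
    """Fraction of a gene's CHD-typed patients in the outflow-tract category.

    Denominator: patients of ``gene`` with a recorded CHD type; numerator:
    those flagged ``oft_type``. Returns (n_oft, n_with_type, percent).
    """
    sub = cohort[cohort["gene"] == gene]
    typed = sub[sub["chd_type"].astype(str).str.strip().replace("nan", "") != ""]
    n_typed = len(typed)
    if n_typed == 0:
        raise InputError(f"no patients of gene {gene!r} with a recorded CHD type")
    n_oft = int(typed["oft_type"].astype(bool).sum())
    return n_oft, n_typed, round_half_up(100 * n_oft / n_typed, decimals)


def _max_maf(variants: pd.DataFrame) -> np.ndarray:
    """Maximum MAF across reference databases; absent frequency counts as 0
    (novel variant)."""
    present = [c for c in MAF_COLUMNS if c in variants.columns]
    if not present:
        logger.warning("no MAF columns present; treating all variants as novel")
        return np.zeros(len(variants))
    vals = variants[present].apply(pd.to_numeric, errors="coerce").fillna(0.0)
    return vals.max(axis=1).to_numpy(dtype=float)


def damaging_algorithm_count(variants: pd.DataFrame, criteria: FilterCriteria) -> np.ndarray:
    """Per-variant count of in-silico algorithms calling it deleterious."""
    n = len(variants)
    count = np.zeros(n, dtype=int)
    if "sift_call" in variants.columns:
        count += (variants["sift_call"].astype(str).str.upper() == "D").to_numpy()
    else:
        logger.warning("sift_call column absent; treated as non-damaging")
    if "polyphen2_call" in variants.columns:
        count += variants["polyphen2_call"].astype(str).str.upper().isin({"P", "D"}).to_numpy()
    else:
        logger.warning("polyphen2_call column absent; treated as non-damaging")
    if "cadd_phred" in variants.columns:
        cadd = pd.to_numeric(variants["cadd_phred"], errors="coerce").fillna(0.0)
        count += (cadd > criteria.cadd_min).to_numpy()
    else:
        logger.warning("cadd_phred column absent; treated as non-damaging")
    return count


def filter_coding_variants(
    variants: pd.DataFrame, criteria: FilterCriteria | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the three-step coding prioritization rule.

    Retained iff: consequence is not synonymous, AND max MAF across databases
    is < maf_max, AND (consequence is nonsense/frameshift OR at least
    ``min_deleterious_algorithms`` algorithms call it damaging). Each excluded
    variant is tallied under the first rule it fails.
    """
    criteria = criteria or FilterCriteria()
    cons = variants["consequence"].astype(str).str.lower()
    maf = _max_maf(variants)
    n_damaging = damaging_algorithm_count(variants, criteria)
    is_syn = (cons == "synonymous").to_numpy()
    maf_fail = ~(maf < criteria.maf_max)
    lof = cons.isin(LOF_CONSEQUENCES).to_numpy()
    alg_fail = ~(lof | (n_damaging >= criteria.min_deleterious_algorithms))
    tallies = {
        "synonymous": int(is_syn.sum()),
        "maf": int((~is_syn & maf_fail).sum()),
        "deleteriousness": int((~is_syn & ~maf_fail & alg_fail).sum()),
    }
    keep = ~is_syn & ~maf_fail & ~alg_fail
    retained = variants.loc[keep].reset_index(drop=True)
    tallies["retained"] = len(retained)
    return retained, tallies


def filter_noncoding_variants(
    variants: pd.DataFrame, maf_max: float = 0.001
) -> pd.DataFrame:
    """Noncoding prioritization: MAF < maf_max and at least one of the
    regulatory / splice-site / microRNA-binding effect flags set."""
    maf = _max_maf(variants)
    flags = np.zeros(len(variants), dtype=bool)
    for col in ("regulatory_flag", "splice_flag", "mirna_flag"):
        if col in variants.columns:
            flags |= variants[col].astype(bool).to_numpy()
    keep = (maf < maf_max) & flags
    return variants.loc[keep].reset_index(drop=True)


def relative_expression_ddct(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative qPCR quantification, 2^-ddCt.

    ddCt = (Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl);
    the returned value is the fold change of the target in the case sample
    relative to control, normalized to the reference gene.
    """
    for v in (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
        if not np.isfinite(v):
            raise InputError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
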