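"""Cell QC, bimod likelihood-ratio differential expression, down-gene
selection, and gene-set intersection.

The bimod test models per-gene log-transformed expression as a mixture: a cell
expresses the gene with probability pi, and expressed values are
Normal(mu, sigma^2); zeros (values at or below the expression threshold) carry
only the 1 - pi mass. The alternative allows group-specific (pi_g, mu_g) with
a pooled sigma; the null shares (pi, mu). The statistic is twice the
log-likelihood gap and is referred to chi-square with 2 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Genes x cells expression values plus per-cell metadata.

    ``meta`` is indexed like ``cells`` and carries at least ``group``; QC uses
    ``n_genes_detected`` and ``mito_fraction`` (detected-gene counts are
    computed from the matrix when absent).
    """

    values: np.ndarray  # shape (n_genes, n_cells), non-negative
    genes: list[str]
    cells: list[str]
    meta: pd.DataFrame

    def __post_init__(self):
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise InputError("matrix dimensions inconsistent with gene/cell labels")
        if len(self.meta) != len(self.cells):
            raise InputError("metadata rows inconsistent with cell labels")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise InputError("matrix values must be finite and non-negative")

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        idx = np.flatnonzero(mask)
        return CountMatrix(
            values=self.values[:, idx],
            genes=self.genes,
            cells=[self.cells[i] for i in idx],
            meta=self.meta.iloc[idx].copy(),
        )


@dataclass(frozen=True)
class GeneSet:
    label: str
    genes: frozenset[str]
    provenance: str = ""

    def __len__(self):
        return len(self.genes)


def qc_filter_cells(
    matrix: CountMatrix, min_genes: int = 200, max_mito: float = 0.25
) -> tuple[CountMatrix, dict[str, int]]:
    """Keep cells with detected genes > ``min_genes`` AND mitochondrial
    fraction < ``max_mito``; report counts removed per rule."""
    meta = matrix.meta
    if "n_genes_detected" in meta.columns:
        n_genes = meta["n_genes_detected"].to_numpy()
    else:
        n_genes = (matrix.values > 0).sum(axis=0)
    if "mito_fraction" in meta.columns:
        mito = meta["mito_fraction"].to_numpy(dtype=float)
    else:
        mito = np.zeros(len(matrix.cells))
    low_genes = n_genes <= min_genes
    high_mito = mito >= max_mito
    keep = ~(low_genes | high_mito)
    report = {
        "removed_low_genes": int(low_genes.sum()),
        "removed_high_mito": int(high_mito.sum()),
        "removed_total": int((~keep).sum()),
        "kept": int(keep.sum()),
    }
    if report["kept"] == 0:
        logger.warning("QC filter removed every cell")
    return matrix.subset_cells(keep), report


def _binomial_ll(n1: np.ndarray, n0: np.ndarray) -> np.ndarray:
    """Maximized Bernoulli log-likelihood n1*log(p) + n0*log(1-p), p = n1/(n1+n0)."""
    n = n1 + n0
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(n1 > 0, n1 * np.log(np.where(n1 > 0, n1, 1) / n), 0.0)
        t0 = np.where(n0 > 0, n0 * np.log(np.where(n0 > 0, n0, 1) / n), 0.0)
    return t1 + t0


def bimod_test(
    matrix: CountMatrix,
    group_a: str,
    group_b: str,
    expression_threshold: float = 0.0,
) -> pd.DataFrame:
    """Zero-inflated likelihood-ratio DE test per gene, vectorized over genes.

    Values are log1p-transformed; cells with transformed expression strictly
    above ``expression_threshold`` count as expressing. The reported log2 fold
    change is the pseudocounted ratio of group means on the original scale
    (zeros included, so dropout and expression shifts both move it), group_b
    relative to group_a. Genes expressed in no cell of either group get p = 1.
    """
    groups = matrix.meta["group"].to_numpy()
    mask_a = groups == group_a
    mask_b = groups == group_b
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise InputError(
            f"both groups need >= 2 cells (got {int(mask_a.sum())} {group_a!r}, "
            f"{int(mask_b.sum())} {group_b!r})"
        )
    x = np.log1p(matrix.values)
    A = x[:, mask_a]
    B = x[:, mask_b]
    posA = A > expression_threshold
    posB = B > expression_threshold
    nA, nB = A.shape[1], B.shape[1]
    nA1 = posA.sum(axis=1).astype(float)
    nB1 = posB.sum(axis=1).astype(float)
    nA0, nB0 = nA - nA1, nB - nB1

    stat_bin = 2.0 * (
        _binomial_ll(nA1, nA0)
        + _binomial_ll(nB1, nB0)
        - _binomial_ll(nA1 + nB1, nA0 + nB0)
    )

    sumA = np.where(posA, A, 0.0).sum(axis=1)
    sumB = np.where(posB, B, 0.0).sum(axis=1)
    sqA = np.where(posA, A * A, 0.0).sum(axis=1)
    sqB = np.where(posB, B * B, 0.0).sum(axis=1)
    npos = nA1 + nB1
    with np.errstate(divide="ignore", invalid="ignore"):
        muA = np.where(nA1 > 0, sumA / np.maximum(nA1, 1), 0.0)
        muB = np.where(nB1 > 0, sumB / np.maximum(nB1, 1), 0.0)
        mu0 = np.where(npos > 0, (sumA + sumB) / np.maximum(npos, 1), 0.0)
    sse_alt = (sqA - nA1 * muA**2) + (sqB - nB1 * muB**2)
    sse_null = (sqA + sqB) - npos * mu0**2
    sse_alt = np.maximum(sse_alt, 0.0)
    sse_null = np.maximum(sse_null, 0.0)
    # pooled sigma^2 from the alternative (group-means) fit, plugged into both
    sigma2 = np.where(npos > 0, sse_alt / np.maximum(npos, 1), 0.0)
    gap = sse_null - sse_alt
    stat_norm = np.where(
        sigma2 > 1e-12,
        gap / np.maximum(sigma2, 1e-12),
        np.where(gap > 1e-12, 1e4, 0.0),  # perfect separation of expressed means
    )
    stat = np.maximum(stat_bin, 0.0) + np.maximum(stat_norm, 0.0)
    pvalue = stats.chi2.sf(stat, df=2)
    pvalue = np.where(npos == 0, 1.0, pvalue)
    stat = np.where(npos == 0, 0.0, stat)

    mean_a = matrix.values[:, mask_a].mean(axis=1)
    mean_b = matrix.values[:, mask_b].mean(axis=1)
    log2fc = np.log2(mean_b + 1.0) - np.log2(mean_a + 1.0)
    return pd.DataFrame(
        {
            "gene_id": matrix.genes,
            "log2fc": log2fc,
            "statistic": stat,
            "pvalue": pvalue,
            "direction": np.where(log2fc < 0, "down", np.where(log2fc > 0, "up", "flat")),
            "pct_expressed_a": nA1 / nA,
            "pct_expressed_b": nB1 / nB,
        }
    )


def select_down_genes(
    de: pd.DataFrame,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    label: str = "down",
) -> GeneSet:
    """Down-regulated gene selection: fold change > ``fc_threshold`` in the
    down direction and p < ``p_threshold`` (both strict)."""
    for col in ("gene_id", "log2fc", "pvalue"):
        if col not in de.columns:
            raise InputError(f"DE table missing column {col!r}")
    fold_down = np.power(2.0, -de["log2fc"].to_numpy(dtype=float))
    keep = (
        (de["log2fc"].to_numpy(dtype=float) < 0)
        & (fold_down > fc_threshold)
        & (de["pvalue"].to_numpy(dtype=float) < p_threshold)
    )
    genes = frozenset(de.loc[keep, "gene_id"])
    return GeneSet(label=label, genes=genes, provenance=f"FC>{fc_threshold}, p<{p_threshold}")


def normalize_symbol(symbol: str) -> str:
    """Case-normalize a gene symbol to mouse-style Title case (NOTCH2 -> Notch2)."""
    s = symbol.strip()
    return s[:1].upper() + s[1:].lower() if s else s


def intersect_sets(sets: list[GeneSet]) -> tuple[GeneSet, dict[str, int]]:
    """Exact intersection of >= 2 gene sets after symbol case-normalization,
    plus Venn region counts (region key = '110' style membership mask; counts
    sum to the union size)."""
    if len(sets) < 2:
        raise InputError("need at least 2 gene sets to intersect")
    normalized = [frozenset(normalize_symbol(g) for g in s.genes) for s in sets]
    union = frozenset().union(*normalized)
    venn: dict[str, int] = {}
    for g in union:
        key = "".join("1" if g in ns else "0" for ns in normalized)
        venn[key] = venn.get(key, 0) + 1
    inter = frozenset.intersection(*normalized)
    label = " & ".join(s.label for s in sets)
    return GeneSet(label=label, genes=inter, provenance="intersection"), venn
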