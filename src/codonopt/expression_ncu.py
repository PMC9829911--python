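"""RNA-seq normalization, demand-weighted codon usage, and abundance binning.

The transcriptome-level demand for a codon weights each gene's codon
count by that gene's abundance:

    ncu_i = sum_j C_ij * a_j / sum_i sum_j C_ij * a_j
    nCU_i = ncu_i / max(ncu)

with a_j = log2(CPM_j + pseudocount). When all genes are equally
abundant the weights cancel and nCU collapses to genomic CU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .codon_core import CodonCountMatrix, CodonUsageVector

logger = logging.getLogger(__name__)


@dataclass
class ExpressionTable:
    """Per-gene abundance: raw counts and a_j = log2(CPM + pseudocount)."""

    a: pd.Series  # gene_id -> log2 normalized abundance
    raw: pd.Series  # gene_id -> raw count

    @property
    def gene_ids(self) -> list[str]:
        return list(self.a.index)

    @classmethod
    def from_tsv(cls, path: str | Path, pseudocount: float = 1.0) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        counts = pd.Series(df["count"].to_numpy(), index=df["gene_id"])
        return normalize_rna_counts(counts.to_dict(), pseudocount)


@dataclass
class AbundanceBins:
    """Genes partitioned into near-equal bins, lowest -> highest abundance."""

    bins: list[list[str]]
    n_bins: int

    def __iter__(self):
        return iter(self.bins)

    @property
    def lowest(self) -> list[str]:
        return self.bins[0]

    @property
    def highest(self) -> list[str]:
        return self.bins[-1]


def normalize_rna_counts(
    raw_counts: Mapping[str, float], pseudocount: float = 1.0
) -> ExpressionTable:
    """a_j = log2(CPM_j + pseudocount)."""
    if len(raw_counts) == 0:
        raise ValueError("empty count table")
    raw = pd.Series(dict(raw_counts), dtype=float)
    if (raw < 0).any():
        raise ValueError("negative count")
    depth = raw.sum()
    if depth == 0:
        raise ValueError("all counts are zero")
    cpm = raw / depth * 1e6
    with np.errstate(divide="ignore"):
        a = pd.Series(np.log2(cpm + pseudocount), index=raw.index)
    return ExpressionTable(a=a, raw=raw)


def abundance_weighted_usage(
    counts: CodonCountMatrix, expr: ExpressionTable
) -> CodonUsageVector:
    """Demand-weighted codon usage over the genes shared by both inputs."""
    shared = [g for g in counts.gene_ids if g in expr.a.index]
    dropped = len(counts.gene_ids) - len(shared)
    if dropped:
        logger.info("abundance_weighted_usage: dropped %d genes without expression", dropped)
    if not shared:
        raise ValueError("no overlap between codon counts and expression table")
    C = counts.counts[shared].to_numpy(dtype=float)
    a = expr.a.loc[shared].to_numpy(dtype=float)
    weighted = C @ a
    denom = weighted.sum()
    if denom == 0:
        raise ValueError("zero denominator: all weighted counts vanish")
    raw = pd.Series(weighted / denom, index=counts.counts.index)
    return CodonUsageVector(raw=raw, relative=raw / raw.max(), flavor="abundance-weighted")


def bin_by_abundance(expr: ExpressionTable, n_bins: int = 10) -> AbundanceBins:
    """Sort genes by a_j (ties broken by gene id) and split into
    ``n_bins`` near-equal groups, lowest abundance first."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    genes = list(expr.a.index)
    if n_bins > len(genes):
        raise ValueError(f"n_bins={n_bins} exceeds gene count {len(genes)}")
    order = sorted(genes, key=lambda g: (expr.a[g], g))
    splits = np.array_split(np.array(order, dtype=object), n_bins)
    bins = [list(chunk) for chunk in splits]
    return AbundanceBins(bins=bins, n_bins=n_bins)


@dataclass
class BinUsageReport:
    """Per-bin distributions of per-mRNA frequency of one codon."""

    codon: str
    per_bin_frequencies: list[np.ndarray]  # aligned with bins, lowest first
    medians: list[float]
    p_value: float  # two-sided Mann-Whitney U, bottom vs top bin

    def summary(self) -> dict:
        return {
            "codon": self.codon,
            "medians": self.medians,
            "bottom_vs_top_p": self.p_value,
        }


def bin_usage_comparison(
    bins: AbundanceBins, counts: CodonCountMatrix, codon: str
) -> BinUsageReport:
    """Compare a codon's per-mRNA usage frequency across abundance bins.

    Frequency for gene j is C_ij divided by the gene's total counted
    codons; the reported p-value is a two-sided rank-sum test of the
    lowest-abundance bin against the highest.
    """
    if codon not in counts.counts.index:
        raise ValueError(f"codon {codon} not in codon space")
    gene_totals = counts.per_gene_totals()
    row = counts.counts.loc[codon]
    freq_all = row / gene_totals.replace(0, np.nan)

    per_bin: list[np.ndarray] = []
    for bin_genes in bins:
        if not bin_genes:
            raise ValueError("empty abundance bin")
        vals = freq_all.reindex(bin_genes).dropna().to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError("bin has no genes with counted codons")
        per_bin.append(vals)
    medians = [float(np.median(v)) for v in per_bin]
    pooled = np.concatenate([per_bin[0], per_bin[-1]])
    if np.ptp(pooled) == 0:  # all values tied: zero rank variance, trivially null
        p_value = 1.0
    else:
        res = stats.mannwhitneyu(
            per_bin[0], per_bin[-1], alternative="two-sided", use_continuity=False
        )
        p_value = float(res.pvalue)
    return BinUsageReport(
        codon=codon,
        per_bin_frequencies=per_bin,
        medians=medians,
        p_value=p_value,
    )
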