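"""Codon and mRNA optimality: tRNA supply over demand.

A codon whose tRNA supply (TAc) exceeds its transcriptome demand (nCU)
is optimal; the log-ratio gives the score a sign:

    cOpt_i = log2(TAc_i / nCU_i)      (> 0 optimal, < 0 suboptimal)

Per-mRNA optimality aggregates cOpt over the gene's codons; by default
the sum is divided by the gene's codon count so that mOpt does not
scale with gene length, then scaled by the maximum absolute raw value
across mRNAs so that the sign convention (higher = more optimal) is
preserved. Distributional outliers are fenced at 1.5 interquartile
ranges beyond the quartiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_core import CodonCountMatrix, CodonUsageVector
from .genetic_code import amino_acid
from .wobble_tai import TAcVector

logger = logging.getLogger(__name__)


def codon_optimality(
    tac: TAcVector, ncu: CodonUsageVector, zero_floor: float | None = None
) -> pd.Series:
    """cOpt_i = log2(TAc_i / nCU_i) over the shared codon space.

    ``zero_floor`` substitutes for nCU_i = 0 (a codon never used in the
    weighted transcriptome) with a warning; without it a zero raises.
    """
    if set(tac.codon_space) != set(ncu.codon_space):
        raise ValueError("TAc and nCU codon spaces differ")
    order = list(tac.codon_space)
    supply = tac.TAc.loc[order].to_numpy(dtype=float)
    demand = ncu.relative.loc[order].to_numpy(dtype=float).copy()
    zero = demand == 0
    if zero.any():
        if zero_floor is None:
            raise ValueError(
                f"nCU is zero for codons {list(np.array(order)[zero])}; "
                "pass zero_floor to substitute"
            )
        logger.warning(
            "substituting nCU floor %g for %d unused codons", zero_floor, zero.sum()
        )
        demand[zero] = zero_floor
    return pd.Series(np.log2(supply / demand), index=order)


def mrna_optimality(
    counts: CodonCountMatrix, copt: pd.Series, length_normalize: bool = True
) -> tuple[pd.Series, pd.Series]:
    """Aggregate cOpt per mRNA.

    Returns ``(mOpt_raw, mOpt)``: the raw per-gene score (sum of
    C_ij * cOpt_i, divided by the gene's codon count when
    ``length_normalize``) and the same scaled by max_j |mOpt_raw_j|.
    Genes with zero counted codons are excluded with a warning.
    """
    missing = set(counts.counts.index) - set(copt.index)
    if missing:
        raise ValueError(f"codons without a cOpt value: {sorted(missing)}")
    w = copt.loc[counts.counts.index].to_numpy(dtype=float)
    C = counts.counts.to_numpy(dtype=float)
    raw_sum = w @ C
    totals = C.sum(axis=0)
    keep = totals > 0
    if (~keep).any():
        logger.warning("excluding %d genes with zero counted codons", (~keep).sum())
    gene_ids = np.array(counts.gene_ids, dtype=object)[keep]
    raw = raw_sum[keep] / totals[keep] if length_normalize else raw_sum[keep]
    mopt_raw = pd.Series(raw, index=list(gene_ids))
    scale = np.abs(mopt_raw).max()
    mopt = mopt_raw / scale if scale > 0 else mopt_raw.copy()
    return mopt_raw, mopt


@dataclass
class OutlierResult:
    cutoff_low: float
    cutoff_high: float
    outliers_low: set[str]
    outliers_high: set[str]


def flag_outliers(mopt: pd.Series) -> OutlierResult:
    """Tukey fences: strictly beyond Q1 - 1.5 IQR / Q3 + 1.5 IQR.

    Quartiles use linear interpolation (numpy default, type 7); the
    convention matters because outlier counts are sensitive to it.
    """
    if len(mopt) < 4:
        raise ValueError("need at least 4 values to fence outliers")
    q1, q3 = np.percentile(mopt.to_numpy(dtype=float), [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return OutlierResult(
        cutoff_low=float(lo),
        cutoff_high=float(hi),
        outliers_low=set(mopt.index[mopt < lo]),
        outliers_high=set(mopt.index[mopt > hi]),
    )


@dataclass
class OptimalityTable:
    """Joint per-codon and per-gene optimality with outlier calls."""

    cOpt: pd.Series
    mOpt_raw: pd.Series
    mOpt: pd.Series
    cutoff_low: float
    cutoff_high: float
    outliers_low: set[str]
    outliers_high: set[str]
    conventions: dict = field(default_factory=dict)

    @classmethod
    def compute(
        cls,
        counts: CodonCountMatrix,
        tac: TAcVector,
        ncu: CodonUsageVector,
        length_normalize: bool = True,
        zero_floor: float | None = None,
    ) -> "OptimalityTable":
        copt = codon_optimality(tac, ncu, zero_floor=zero_floor)
        mopt_raw, mopt = mrna_optimality(counts, copt, length_normalize)
        fences = flag_outliers(mopt)
        return cls(
            cOpt=copt,
            mOpt_raw=mopt_raw,
            mOpt=mopt,
            cutoff_low=fences.cutoff_low,
            cutoff_high=fences.cutoff_high,
            outliers_low=fences.outliers_low,
            outliers_high=fences.outliers_high,
            conventions={
                "length_normalize": length_normalize,
                "mOpt_scaling": "raw / max(|raw|)",
                "quartiles": "linear interpolation (type 7)",
            },
        )

    def codon_table(self, tac: TAcVector, ncu: CodonUsageVector) -> pd.DataFrame:
        order = list(self.cOpt.index)
        return pd.DataFrame(
            {
                "codon": order,
                "amino_acid": [amino_acid(c) for c in order],
                "TAc": tac.TAc.loc[order].to_numpy(),
                "nCU": ncu.relative.loc[order].to_numpy(),
                "cOpt": self.cOpt.to_numpy(),
                "optimal_flag": (self.cOpt > 0).to_numpy(),
            }
        )

    def gene_table(self) -> pd.DataFrame:
        flags = []
        for g in self.mOpt.index:
            if g in self.outliers_low:
                flags.append("low")
            elif g in self.outliers_high:
                flags.append("high")
            else:
                flags.append("none")
        return pd.DataFrame(
            {
                "gene_id": self.mOpt.index,
                "mOpt_raw": self.mOpt_raw.loc[self.mOpt.index].to_numpy(),
                "mOpt": self.mOpt.to_numpy(),
                "outlier_flag": flags,
            }
        )

    def write(self, out_dir: str | Path, tac: TAcVector, ncu: CodonUsageVector) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.codon_table(tac, ncu).to_csv(out / "codon_optimality.tsv", sep="\t", index=False)
        self.gene_table().to_csv(out / "mrna_optimality.tsv", sep="\t", index=False)
        import json

        (out / "optimality_cutoffs.json").write_text(
            json.dumps(
                {
                    "cutoff_low": self.cutoff_low,
                    "cutoff_high": self.cutoff_high,
                    "n_outliers_low": len(self.outliers_low),
                    "n_outliers_high": len(self.outliers_high),
                    "conventions": self.conventions,
                },
                indent=2,
            )
        )
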