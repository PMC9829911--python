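"""tRNA abundance from per-anticodon sequencing read counts.

Hybridization-free tRNA sequencing (partial digestion + small-RNA
library) yields read counts per annotated tRNA gene; in an organism
with single-copy tRNA genes these collapse to one count per anticodon.
Counts are library-normalized to counts-per-million per replicate,
averaged across replicates, and log2-transformed — the resulting
``abundance`` is the tRNC term of the adaptiveness sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

_VALID_BASES = frozenset("ACGT")


@dataclass
class AnticodonCountTable:
    """Per-anticodon read counts per replicate, plus the isotype map."""

    counts: pd.DataFrame  # index = anticodon, columns = replicate ids
    isotype: dict[str, str]  # anticodon -> one-letter or three-letter amino acid

    def __post_init__(self) -> None:
        for ac in self.counts.index:
            if len(ac) != 3 or not set(ac) <= _VALID_BASES:
                raise ValueError(f"invalid anticodon {ac!r}")
        if self.counts.shape[1] < 1:
            raise ValueError("at least one replicate required")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read count")
        missing = set(self.counts.index) - set(self.isotype)
        if missing:
            raise ValueError(f"anticodons without isotype: {sorted(missing)}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnticodonCountTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        wide = df.pivot_table(
            index="anticodon", columns="replicate", values="read_count", fill_value=0
        ).astype("int64")
        isotype = dict(zip(df["anticodon"], df["amino_acid"]))
        return cls(counts=wide, isotype=isotype)

    def to_tsv(self, path: str | Path) -> None:
        long = self.counts.rename_axis("anticodon").reset_index().melt(
            id_vars="anticodon", var_name="replicate", value_name="read_count"
        )
        long["amino_acid"] = long["anticodon"].map(self.isotype)
        long = long[["anticodon", "amino_acid", "replicate", "read_count"]]
        long.to_csv(path, sep="\t", index=False)


@dataclass
class TrnaAbundance:
    """log2(mean CPM + pseudocount) per anticodon."""

    abundance: pd.Series  # anticodon -> abundance
    normalization_label: str = "log2(mean CPM + pseudocount)"
    mean_cpm: pd.Series | None = None

    def __getitem__(self, anticodon: str) -> float:
        return float(self.abundance[anticodon])

    def to_tsv(self, path: str | Path, isotype: dict[str, str] | None = None) -> None:
        df = pd.DataFrame(
            {
                "anticodon": self.abundance.index,
                "amino_acid": [
                    (isotype or {}).get(ac, "NA") for ac in self.abundance.index
                ],
                "mean_cpm": (
                    self.mean_cpm.reindex(self.abundance.index).to_numpy()
                    if self.mean_cpm is not None
                    else np.nan
                ),
                "abundance": self.abundance.to_numpy(),
            }
        )
        df.to_csv(path, sep="\t", index=False)


def normalize_trna_counts(
    table: AnticodonCountTable,
    pseudocount: float = 1.0,
    extra_anticodons: list[str] | None = None,
) -> TrnaAbundance:
    """CPM per replicate, mean over replicates, then log2(+pseudocount).

    Per-replicate CPM scaling makes replicates of unequal sequencing
    depth commensurable before averaging. Anticodons listed in
    ``extra_anticodons`` but absent from the table receive the
    pseudocount-only abundance (log2(pseudocount)); with pseudocount 1
    that is 0, which feeds the zero-adaptiveness fallback downstream.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    raw = table.counts.astype(float)
    depth = raw.sum(axis=0)
    if (depth == 0).all():
        raise ValueError("all-zero count table")
    cpm = raw / depth.replace(0, np.nan) * 1e6
    mean_cpm = cpm.mean(axis=1, skipna=True).fillna(0.0)
    if extra_anticodons:
        mean_cpm = mean_cpm.reindex(
            sorted(set(mean_cpm.index) | set(extra_anticodons)), fill_value=0.0
        )
    with np.errstate(divide="ignore"):
        abundance = pd.Series(np.log2(mean_cpm + pseudocount), index=mean_cpm.index)
    return TrnaAbundance(abundance=abundance, mean_cpm=mean_cpm)
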