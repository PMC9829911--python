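"""Codon counting over CDS sets and genomic codon usage.

Core quantities
---------------
``C_ij``  — count of codon *i* in mRNA *j* (frame 0, annotated CDS).
``cu_i``  — genomic codon usage, ``sum_j C_ij / N`` with ``N`` the total
            number of counted codons.
``CU_i``  — relative usage, ``cu_i / max(cu)``.

Stop codons are always excluded; the default codon space additionally
drops ATG, leaving the 60 sense codons conventional for tRNA-adaptation
work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from .genetic_code import CODON_SPACE_60, STOP_CODONS, amino_acid

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


@dataclass
class TranscriptSet:
    """A set of annotated coding sequences, one CDS per gene.

    Sequences are normalized on construction: uppercased and U->T.
    Records with internal ambiguity characters are rejected with a
    warning; a length not divisible by 3 is a hard error (the inputs
    are annotated CDS, so a broken frame is a data bug, not noise).
    """

    records: list[tuple[str, str]] = field(default_factory=list)
    organism_label: str = ""

    def __post_init__(self) -> None:
        clean: list[tuple[str, str]] = []
        seen: set[str] = set()
        for gene_id, seq in self.records:
            if gene_id in seen:
                raise ValueError(f"duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            seq = seq.upper().replace("U", "T")
            if len(seq) % 3 != 0:
                raise ValueError(
                    f"CDS length of gene {gene_id!r} is {len(seq)}, not divisible by 3"
                )
            if not set(seq) <= _VALID_BASES:
                bad = sorted(set(seq) - _VALID_BASES)
                logger.warning(
                    "rejecting gene %s: ambiguity characters %s", gene_id, bad
                )
                continue
            clean.append((gene_id, seq))
        self.records = clean

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @classmethod
    def from_fasta(cls, path: str | Path, organism_label: str = "") -> "TranscriptSet":
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        return cls(records=records, organism_label=organism_label)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for gene_id, seq in self.records:
                fh.write(f">{gene_id}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")


@dataclass
class CodonCountMatrix:
    """Per-gene codon counts ``C_ij`` restricted to a fixed codon space."""

    counts: pd.DataFrame  # index = codon_space, columns = gene ids
    codon_space: tuple[str, ...]

    @property
    def total(self) -> int:
        """N — total number of counted codons."""
        return int(self.counts.to_numpy().sum())

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.columns)

    def per_gene_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class CodonUsageVector:
    """Codon usage, raw (sums to 1) and relative to the maximum."""

    raw: pd.Series  # cu_i or ncu_i over codon_space
    relative: pd.Series  # CU_i or nCU_i
    flavor: str  # "genomic" | "abundance-weighted"

    @property
    def codon_space(self) -> tuple[str, ...]:
        return tuple(self.raw.index)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "codon": self.raw.index,
                "amino_acid": [amino_acid(c) for c in self.raw.index],
                "cu": self.raw.to_numpy(),
                "CU": self.relative.to_numpy(),
            }
        )
        df.to_csv(path, sep="\t", index=False)


def count_codons(
    transcripts: TranscriptSet,
    codon_space: Sequence[str] = CODON_SPACE_60,
    include_start_codon: bool = True,
) -> CodonCountMatrix:
    """Count codons per gene in frame 0, restricted to ``codon_space``.

    Stop codons and codons outside the space are dropped from both the
    counts and the total N. ``include_start_codon=False`` skips the
    first codon of every CDS.
    """
    codon_space = tuple(codon_space)
    if set(codon_space) & STOP_CODONS:
        raise ValueError("codon_space must not contain stop codons")
    index = {c: k for k, c in enumerate(codon_space)}
    mat = np.zeros((len(codon_space), len(transcripts)), dtype=np.int64)
    for j, (gene_id, seq) in enumerate(transcripts):
        start = 3 if not include_start_codon else 0
        for p in range(start, len(seq), 3):
            k = index.get(seq[p : p + 3])
            if k is not None:
                mat[k, j] += 1
    counts = pd.DataFrame(mat, index=list(codon_space), columns=transcripts.gene_ids)
    return CodonCountMatrix(counts=counts, codon_space=codon_space)


def genomic_codon_usage(counts: CodonCountMatrix) -> CodonUsageVector:
    """cu_i = sum_j C_ij / N and CU_i = cu_i / cu_max."""
    totals = counts.counts.sum(axis=1).astype(float)
    n = totals.sum()
    if n == 0:
        raise ValueError("no codons counted")
    raw = totals / n
    return CodonUsageVector(raw=raw, relative=raw / raw.max(), flavor="genomic")


@dataclass
class UsageComparison:
    """Spearman rank comparison of two usage vectors over a shared space."""

    coefficient: float
    p_value: float
    paired: pd.DataFrame  # columns: codon, a, b


def compare_usage(a: CodonUsageVector, b: CodonUsageVector) -> UsageComparison:
    """Spearman rank correlation of two usage vectors plus the paired table."""
    if set(a.codon_space) != set(b.codon_space):
        missing_a = sorted(set(b.codon_space) - set(a.codon_space))
        missing_b = sorted(set(a.codon_space) - set(b.codon_space))
        raise ValueError(
            f"codon spaces differ: only-in-b={missing_a}, only-in-a={missing_b}"
        )
    order = list(a.codon_space)
    x = a.relative.loc[order].to_numpy()
    y = b.relative.loc[order].to_numpy()
    rho, p = stats.spearmanr(x, y)
    paired = pd.DataFrame({"codon": order, "a": x, "b": y})
    return UsageComparison(coefficient=float(rho), p_value=float(p), paired=paired)


def merge_transcript_sets(sets: Iterable[TranscriptSet], organism_label: str = "") -> TranscriptSet:
    records: list[tuple[str, str]] = []
    for ts in sets:
        records.extend(ts.records)
    return TranscriptSet(records=records, organism_label=organism_label)
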