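"""Ribosome-profiling preprocessing, P-site offsets, and pause scores.

Footprint 5'-end positions are turned into A-site codon occupancy in
three steps: (1) gene filtering on length and coverage; (2) metagene
estimation of the per-read-length P-site offset from the initiation
peak; (3) codon-wise pause scoring.

For a gene g of L_g codons with per-nucleotide A-site density R_g
(length 3 L_g), the normalization factor and positional pause score
are computed literally as

    F_g  = sum(R_g) / (L_g - 2)
    P_gi = sum(C_gi) / F_g      for interior codons i (first and last ignored)

where C_gi is the density chunk of codon i. Note the literal F_g makes
uniform coverage score (L_g - 2)/L_g, not 1; an interior-only variant
(sum over interior positions only) is available via ``fg_interior``.
A codon's genomic pause score pools positional scores across genes
(per-gene-mean averaging available); per-amino-acid scores are the
unweighted mean over synonymous codons.

Coordinates are 0-based and gene-relative (0 = first base of the start
codon); minus-strand genes must be reverse-complemented upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .codon_core import TranscriptSet
from .genetic_code import amino_acid, synonymous_families

logger = logging.getLogger(__name__)

READ_LENGTH_RANGE = range(26, 36)  # 26..35 nt inclusive


@dataclass
class RiboProfile:
    """Per-gene footprint data.

    ``read_5p_positions`` holds raw footprints as (gene, read_length) ->
    array of 5'-end positions relative to the start codon (may be
    negative); ``per_gene_density`` holds per-nucleotide A-site counts
    once offsets have been applied (length 3 L_g per gene).
    """

    gene_lengths_codons: dict[str, int]
    read_5p_positions: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    per_gene_density: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, dens in self.per_gene_density.items():
            L = self.gene_lengths_codons[g]
            if len(dens) != 3 * L:
                raise ValueError(
                    f"density of gene {g} has length {len(dens)}, expected {3 * L}"
                )
            if (np.asarray(dens) < 0).any():
                raise ValueError(f"negative density in gene {g}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.gene_lengths_codons)

    @classmethod
    def from_read_table(
        cls, df: pd.DataFrame, gene_lengths_codons: Mapping[str, int]
    ) -> "RiboProfile":
        """Build from a long table with columns gene_id, read_length,
        offset (5'-end position relative to start), count."""
        reads: dict[tuple[str, int], np.ndarray] = {}
        for (gene, rlen), sub in df.groupby(["gene_id", "read_length"]):
            pos = np.repeat(sub["offset"].to_numpy(int), sub["count"].to_numpy(int))
            reads[(str(gene), int(rlen))] = pos
        return cls(
            gene_lengths_codons=dict(gene_lengths_codons), read_5p_positions=reads
        )


@dataclass
class PsiteOffsets:
    """Per-read-length P-site offsets and the metagene vectors behind them."""

    offsets: dict[int, int]
    metagene: dict[int, np.ndarray]
    window: tuple[int, int] = (-50, 200)

    def to_json(self, path: str | Path) -> None:
        import json

        Path(path).write_text(
            json.dumps({str(k): v for k, v in sorted(self.offsets.items())}, indent=2)
        )


def filter_genes(
    profile: RiboProfile,
    min_len_nt: int = 100,
    skip_5p_nt: int = 21,
    min_mean_cov: float = 40.0,
) -> RiboProfile:
    """Keep genes long enough and covered deeply enough.

    Mean coverage is computed over positions after the first
    ``skip_5p_nt`` nucleotides (the 5' region is excluded because
    initiation peaks inflate it); both thresholds are inclusive.
    """
    keep: list[str] = []
    for g, dens in profile.per_gene_density.items():
        if len(dens) < min_len_nt:
            continue
        body = np.asarray(dens, dtype=float)[skip_5p_nt:]
        if body.size == 0 or body.mean() < min_mean_cov:
            continue
        keep.append(g)
    if not keep:
        logger.warning("filter_genes: no genes pass the filters")
    kept = set(keep)
    return RiboProfile(
        gene_lengths_codons={g: profile.gene_lengths_codons[g] for g in keep},
        read_5p_positions={
            k: v for k, v in profile.read_5p_positions.items() if k[0] in kept
        },
        per_gene_density={g: profile.per_gene_density[g] for g in keep},
    )


def metagene_psite_offsets(
    profile: RiboProfile, window: tuple[int, int] = (-50, 200)
) -> PsiteOffsets:
    """Estimate the P-site offset per read length from the initiation peak.

    Per read length, each gene contributes a vector of 5'-end counts
    over the half-open window around the start codon, normalized to sum
    1 (so deep genes do not dominate); the metagene is the column-wise
    sum over genes and the offset is the distance from the initiation
    peak to the annotated start (a peak at position -14 gives offset 14).
    """
    lo, hi = window
    width = hi - lo
    offsets: dict[int, int] = {}
    metagenes: dict[int, np.ndarray] = {}
    for rlen in READ_LENGTH_RANGE:
        meta = np.zeros(width, dtype=float)
        n_genes = 0
        for (gene, rl), pos in profile.read_5p_positions.items():
            if rl != rlen:
                continue
            inside = pos[(pos >= lo) & (pos < hi)]
            if inside.size == 0:
                continue
            vec = np.bincount(inside - lo, minlength=width).astype(float)
            meta += vec / vec.sum()
            n_genes += 1
        if n_genes == 0:
            logger.info("no reads of length %d in the window; offset absent", rlen)
            continue
        peak = int(np.argmax(meta)) + lo
        offsets[rlen] = -peak
        metagenes[rlen] = meta
    return PsiteOffsets(offsets=offsets, metagene=metagenes, window=window)


def assign_asite_density(
    profile: RiboProfile, offsets: PsiteOffsets | Mapping[int, int], a_site_shift: int = 3
) -> RiboProfile:
    """Convert 5'-end reads to per-nucleotide A-site density.

    Each read's occupancy position is 5'-end + P-site offset +
    ``a_site_shift`` (default +3 nt, one codon downstream of the
    P site; pass 0 for P-site scoring). Reads landing outside the gene
    body are discarded.
    """
    table = offsets.offsets if isinstance(offsets, PsiteOffsets) else dict(offsets)
    density = {
        g: np.zeros(3 * L, dtype=float)
        for g, L in profile.gene_lengths_codons.items()
    }
    for (gene, rlen), pos in profile.read_5p_positions.items():
        if rlen not in table:
            continue
        sites = pos + table[rlen] + a_site_shift
        n = len(density[gene])
        sites = sites[(sites >= 0) & (sites < n)]
        density[gene] += np.bincount(sites, minlength=n)
    return RiboProfile(
        gene_lengths_codons=dict(profile.gene_lengths_codons),
        read_5p_positions=dict(profile.read_5p_positions),
        per_gene_density=density,
    )


@dataclass
class PauseTable:
    """Positional, per-codon (genomic) and per-amino-acid pause scores."""

    positional: pd.DataFrame  # columns: gene_id, codon_index, codon, score
    genomic: pd.Series  # codon -> mean pause
    by_amino_acid: pd.Series  # amino acid -> mean over synonymous codons
    F: pd.Series  # gene -> normalization factor

    def to_tsv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(
            {
                "codon": self.genomic.index,
                "amino_acid": [amino_acid(c) for c in self.genomic.index],
                "pause_score": self.genomic.to_numpy(),
            }
        )
        df.to_csv(out / "codon_pause_scores.tsv", sep="\t", index=False)
        self.by_amino_acid.rename("pause_score").rename_axis("amino_acid").to_csv(
            out / "amino_acid_pause_scores.tsv", sep="\t"
        )


def pause_scores(
    profile: RiboProfile,
    transcripts: TranscriptSet,
    genomic_mean: str = "pooled",
    fg_interior: bool = False,
) -> PauseTable:
    """Codon-wise pause scores from A-site density.

    The profile must already be filtered and carry A-site density.
    ``genomic_mean`` is "pooled" (mean over all positional scores with
    that codon, across genes) or "per-gene" (mean of per-gene means).
    ``fg_interior`` computes F_g over interior positions only instead
    of the literal full-vector sum.
    """
    if genomic_mean not in ("pooled", "per-gene"):
        raise ValueError("genomic_mean must be 'pooled' or 'per-gene'")
    seqs = dict(transcripts.records)
    rows: list[tuple[str, int, str, float]] = []
    F: dict[str, float] = {}
    for gene, dens in profile.per_gene_density.items():
        if gene not in seqs:
            raise KeyError(f"gene {gene} has density but no CDS sequence")
        dens = np.asarray(dens, dtype=float)
        L = profile.gene_lengths_codons[gene]
        if L < 3:
            continue
        body = dens[3 : 3 * (L - 1)] if fg_interior else dens
        fg = body.sum() / (L - 2)
        if fg == 0:
            logger.warning("gene %s has zero coverage; skipped", gene)
            continue
        F[gene] = fg
        chunk_sums = dens.reshape(L, 3).sum(axis=1)
        seq = seqs[gene]
        for i in range(1, L - 1):  # first and last codons ignored
            codon = seq[3 * i : 3 * i + 3]
            rows.append((gene, i, codon, chunk_sums[i] / fg))
    positional = pd.DataFrame(rows, columns=["gene_id", "codon_index", "codon", "score"])
    if positional.empty:
        raise ValueError("no positional pause scores could be computed")
    if genomic_mean == "pooled":
        genomic = positional.groupby("codon")["score"].mean()
    else:
        genomic = (
            positional.groupby(["codon", "gene_id"])["score"].mean().groupby("codon").mean()
        )
    by_aa = amino_acid_pause(genomic)
    return PauseTable(
        positional=positional,
        genomic=genomic,
        by_amino_acid=by_aa,
        F=pd.Series(F),
    )


def amino_acid_pause(genomic: pd.Series) -> pd.Series:
    """Unweighted mean of genomic pause scores over synonymous codons.

    Codons never observed are simply absent from ``genomic``; the mean
    is then over the observed members of the family.
    """
    fams = synonymous_families()
    out: dict[str, float] = {}
    for aa, codons in fams.items():
        present = [c for c in codons if c in genomic.index]
        if not present:
            continue
        if len(present) < len(codons):
            logger.info(
                "amino acid %s: %d/%d synonymous codons observed",
                aa, len(present), len(codons),
            )
        out[aa] = float(genomic.loc[present].mean())
    return pd.Series(out).sort_index()


def translation_efficiency(
    ribo_counts: Mapping[str, float],
    rna_counts: Mapping[str, float],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2 ratio of footprint CPM to mRNA CPM.

    A simple density ratio — not a statistical model of translational
    regulation; it ignores count overdispersion and shared-gene effects
    that dedicated TE estimators model.
    """
    ribo = pd.Series(dict(ribo_counts), dtype=float)
    rna = pd.Series(dict(rna_counts), dtype=float)
    shared = ribo.index.intersection(rna.index)
    if shared.empty:
        raise ValueError("no genes shared between ribo and RNA tables")
    ribo_cpm = ribo.loc[shared] / ribo.loc[shared].sum() * 1e6
    rna_cpm = rna.loc[shared] / rna.loc[shared].sum() * 1e6
    return pd.Series(
        np.log2((ribo_cpm + pseudocount) / (rna_cpm + pseudocount)), index=shared
    )
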