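"""Seeded generators for every pipeline input, with known ground truth.

The generators emulate the study conditions of a slow-growing
bacterium with single-copy tRNA genes: a pool of ~45 anticodons whose
abundances span an order of magnitude, a GC-biased transcriptome of a
few thousand CDS with a log-scale abundance spread, and ribosome
footprints (26-35 nt) with a known P-site offset per read length and
programmable codon-specific dwell multipliers. Every draw flows from a
single ``numpy.random.Generator`` seeded in the config, so runs are
fully reproducible; ground truth is returned alongside (and written as
a JSON sidecar by the pipeline) so downstream tests are self-checking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .codon_core import TranscriptSet
from .expression_ncu import ExpressionTable, normalize_rna_counts
from .genetic_code import CODON_SPACE_60
from .riboseq_pause import RiboProfile
from .trna_quant import AnticodonCountTable
from .wobble_tai import load_bundled_anticodons

DEFAULT_PSITE_OFFSETS = {26: 11, 27: 11, 28: 12, 29: 12, 30: 13, 31: 13, 32: 14, 33: 14, 34: 15, 35: 15}

#: triangular read-length weights over 26..35, peaked at 30
_READ_LENGTHS = np.arange(26, 36)
_READ_LENGTH_WEIGHTS = np.array([1, 2, 3, 4, 5, 4, 3, 2, 1.5, 1], dtype=float)
_READ_LENGTH_WEIGHTS /= _READ_LENGTH_WEIGHTS.sum()


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study; defaults mirror the emulated data."""

    seed: int = 0
    n_genes: int = 400
    gene_length_range: tuple[int, int] = (100, 300)  # codons, inclusive
    codon_bias: dict[str, float] | None = None  # default: uniform over 60 codons
    trna_abundance_spread: float = 10.0  # max/min fold-range of the pool
    expression_sd_log2: float = 2.0
    psite_offsets_truth: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_PSITE_OFFSETS)
    )
    pause_multipliers: dict[str, float] = field(default_factory=dict)
    reads_per_gene_mean: float = 50.0
    init_peak_weight: float = 0.05  # fraction of footprints from initiating ribosomes
    trna_depth: int = 1_000_000  # reads per tRNA-seq replicate
    rna_depth: int = 5_000_000  # total RNA-seq reads

    def __post_init__(self) -> None:
        if self.trna_abundance_spread < 1:
            raise ValueError("trna_abundance_spread must be >= 1")
        if any(m <= 0 for m in self.pause_multipliers.values()):
            raise ValueError("pause multipliers must be > 0")
        if self.codon_bias is not None:
            extra = set(self.codon_bias) - set(CODON_SPACE_60)
            if extra:
                raise ValueError(f"codon_bias over wrong codon space: {sorted(extra)}")
            total = sum(self.codon_bias.values())
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError(f"codon_bias sums to {total}, expected 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def bias_vector(self) -> pd.Series:
        if self.codon_bias is None:
            return pd.Series(1.0 / len(CODON_SPACE_60), index=list(CODON_SPACE_60))
        return pd.Series(self.codon_bias).reindex(list(CODON_SPACE_60), fill_value=0.0)


def simulate_trna_pool(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[AnticodonCountTable, pd.Series]:
    """Two-replicate anticodon count table plus the true relative pool.

    True abundances are log-uniform over ``trna_abundance_spread``
    (anchored so that min and max hit the ends of the range exactly —
    the pool's dynamic range is a study condition, not a random
    outcome); replicate counts are multinomial at ``trna_depth``.
    """
    rng = rng or config.rng()
    anticodons = load_bundled_anticodons()
    n = len(anticodons)
    if config.trna_abundance_spread == 1.0:
        truth = np.ones(n)
    else:
        u = rng.uniform(0, 1, size=n)
        # pin the extremes so max/min equals the configured spread
        u[np.argmin(u)], u[np.argmax(u)] = 0.0, 1.0
        truth = config.trna_abundance_spread ** u
    truth_p = truth / truth.sum()
    counts = {
        f"rep{r + 1}": rng.multinomial(config.trna_depth, truth_p)
        for r in range(2)
    }
    table = AnticodonCountTable(
        counts=pd.DataFrame(counts, index=anticodons["anticodon"].to_list()),
        isotype=dict(zip(anticodons["anticodon"], anticodons["amino_acid"])),
    )
    truth_series = pd.Series(truth_p, index=anticodons["anticodon"].to_list())
    return table, truth_series


def simulate_transcriptome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[TranscriptSet, ExpressionTable, dict]:
    """CDS set sampled codon-by-codon plus a matching expression table.

    Sequences are ATG + body (codon draws from ``codon_bias``) + TAA;
    the start and stop never enter the 60-codon analysis space. True
    per-gene abundance is log2-normal with sd ``expression_sd_log2``;
    observed counts are one multinomial draw at ``rna_depth``.
    """
    rng = rng or config.rng()
    bias = config.bias_vector()
    codons = np.array(bias.index)
    p = bias.to_numpy()
    records: list[tuple[str, str]] = []
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    width = len(str(config.n_genes - 1))
    for g, L in enumerate(lengths):
        body = rng.choice(codons, size=L, p=p)
        records.append((f"g{g:0{width}d}", "ATG" + "".join(body) + "TAA"))
    transcripts = TranscriptSet(records=records, organism_label="synthetic")

    log2_expr = rng.normal(0.0, config.expression_sd_log2, size=config.n_genes)
    expr_p = np.exp2(log2_expr)
    expr_p /= expr_p.sum()
    raw = rng.multinomial(config.rna_depth, expr_p)
    gene_ids = [g for g, _ in records]
    expr = normalize_rna_counts(dict(zip(gene_ids, raw.astype(float))))
    truth = {
        "true_log2_expression": dict(zip(gene_ids, log2_expr.tolist())),
        "gene_lengths_codons": dict(zip(gene_ids, (lengths + 2).tolist())),
    }
    return transcripts, expr, truth


def simulate_binned_transcriptome(
    config: SimulationConfig,
    enriched_codon: str,
    enrichment: float = 2.0,
    rng: np.random.Generator | None = None,
) -> tuple[TranscriptSet, ExpressionTable]:
    """Transcriptome where the most-abundant half of genes uses
    ``enriched_codon`` at ``enrichment`` times its baseline frequency —
    the planted signal for bin-vs-bin usage comparisons."""
    rng = rng or config.rng()
    base = config.bias_vector()
    rich = base.copy()
    rich[enriched_codon] *= enrichment
    rich /= rich.sum()

    log2_expr = np.sort(rng.normal(0.0, config.expression_sd_log2, size=config.n_genes))
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    half = config.n_genes // 2
    codons = np.array(base.index)
    width = len(str(config.n_genes - 1))
    records = []
    for g, L in enumerate(lengths):
        p = (rich if g >= half else base).to_numpy()
        body = rng.choice(codons, size=L, p=p)
        records.append((f"g{g:0{width}d}", "ATG" + "".join(body) + "TAA"))
    transcripts = TranscriptSet(records=records, organism_label="synthetic-binned")
    expr_p = np.exp2(log2_expr)
    expr_p /= expr_p.sum()
    raw = rng.multinomial(config.rna_depth, expr_p)
    gene_ids = [g for g, _ in records]
    expr = normalize_rna_counts(dict(zip(gene_ids, raw.astype(float))))
    return transcripts, expr


def simulate_ribo_profile(
    transcripts: TranscriptSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, RiboProfile]:
    """Footprint 5'-end table with programmed offsets and codon dwells.

    Per gene, each interior codon carries a dwell weight
    ``pause_multipliers[codon]`` (default 1); the gene's read count is
    Poisson(``reads_per_gene_mean``) and elongating reads land on
    codons multinomially by dwell weight. A fraction
    ``init_peak_weight`` of footprints comes from initiating ribosomes
    whose P site sits on the start codon — the sharp metagene peak the
    P-site offset estimator relies on. Each read draws a length from
    the triangular 26-35 distribution and places its 5' end at
    A-site - (offset + 3) for that length's true offset (initiating
    reads at -offset).

    Returns the long read table (gene_id, read_length, offset, count)
    and the equivalent RiboProfile.
    """
    rng = rng or config.rng()
    offsets = config.psite_offsets_truth
    missing = set(_READ_LENGTHS.tolist()) - set(offsets)
    if missing:
        raise ValueError(f"psite_offsets_truth missing read lengths {sorted(missing)}")
    mult = config.pause_multipliers
    rows: list[tuple[str, int, int, int]] = []
    gene_lengths: dict[str, int] = {}
    for gene_id, seq in transcripts:
        L = len(seq) // 3
        gene_lengths[gene_id] = L
        weights = np.array(
            [mult.get(seq[3 * i : 3 * i + 3], 1.0) for i in range(1, L - 1)]
        )
        n_reads = rng.poisson(config.reads_per_gene_mean)
        if n_reads == 0 or weights.sum() == 0:
            continue
        n_init = rng.binomial(n_reads, config.init_peak_weight)
        rlens = rng.choice(_READ_LENGTHS, size=n_reads, p=_READ_LENGTH_WEIGHTS)
        for r in range(n_init):  # initiating ribosome: P site on the start codon
            rlen = int(rlens[r])
            rows.append((gene_id, rlen, -offsets[rlen], 1))
        codon_hits = rng.multinomial(n_reads - n_init, weights / weights.sum())
        read_idx = n_init
        for k, hits in enumerate(codon_hits):
            a_site = 3 * (k + 1)  # interior codon k+1
            for _ in range(hits):
                rlen = int(rlens[read_idx])
                read_idx += 1
                five_p = a_site - (offsets[rlen] + 3)
                rows.append((gene_id, rlen, five_p, 1))
    df = pd.DataFrame(rows, columns=["gene_id", "read_length", "offset", "count"])
    df = (
        df.groupby(["gene_id", "read_length", "offset"], as_index=False)["count"].sum()
        if not df.empty
        else df
    )
    profile = RiboProfile.from_read_table(df, gene_lengths) if not df.empty else RiboProfile(
        gene_lengths_codons=gene_lengths
    )
    return df, profile


def write_simulation_bundle(
    out_dir: str | Path, config: SimulationConfig
) -> dict[str, Path]:
    """Generate every pipeline input under ``out_dir`` with a ground-truth
    sidecar JSON; returns the paths keyed by role."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = config.rng()
    table, pool_truth = simulate_trna_pool(config, rng)
    transcripts, expr, truth = simulate_transcriptome(config, rng)
    read_df, _ = simulate_ribo_profile(transcripts, config, rng)

    paths = {
        "cds_fasta": out / "cds.fasta",
        "trna_counts": out / "trna_counts.tsv",
        "rna_counts": out / "rna_counts.tsv",
        "ribo_reads": out / "ribo_reads.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    transcripts.to_fasta(paths["cds_fasta"])
    table.to_tsv(paths["trna_counts"])
    pd.DataFrame(
        {"gene_id": expr.raw.index, "count": expr.raw.astype(int).to_numpy()}
    ).to_csv(paths["rna_counts"], sep="\t", index=False)
    read_df.to_csv(paths["ribo_reads"], sep="\t", index=False)
    truth_out = {
        "seed": config.seed,
        "true_trna_pool": pool_truth.to_dict(),
        "psite_offsets": config.psite_offsets_truth,
        "pause_multipliers": config.pause_multipliers,
        **truth,
    }
    paths["ground_truth"].write_text(json.dumps(truth_out, indent=2))
    return paths
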