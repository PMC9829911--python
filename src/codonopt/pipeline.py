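"""End-to-end orchestration: inputs (real or simulated) -> result bundle.

The pipeline is a thin composition of the stage modules — tRNA
quantification -> wobble/TAc -> codon usage and demand weighting ->
optimality, in parallel with ribosome-profiling offsets and pause
scores — with every stage output readable standalone and a manifest
recording the conventions in force. Reruns with an identical manifest
reproduce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .codon_core import (
    CodonUsageVector,
    TranscriptSet,
    compare_usage,
    count_codons,
    genomic_codon_usage,
)
from .expression_ncu import (
    ExpressionTable,
    abundance_weighted_usage,
    bin_by_abundance,
)
from .optimality import OptimalityTable
from .riboseq_pause import (
    PauseTable,
    RiboProfile,
    assign_asite_density,
    filter_genes,
    metagene_psite_offsets,
    pause_scores,
    translation_efficiency,
)
from .synthetic_data import SimulationConfig, simulate_ribo_profile, simulate_transcriptome, simulate_trna_pool
from .trna_quant import AnticodonCountTable, normalize_trna_counts
from .wobble_tai import TAcVector, WobblePenaltySet, compute_tac

logger = logging.getLogger(__name__)

_DEFAULT_OPTIONS: dict[str, Any] = {
    "pseudocount": 1.0,
    "n_bins": 10,
    "length_normalize": True,
    "a_site_shift": 3,
    "fg_interior": False,
    "genomic_mean": "pooled",
    "min_len_nt": 100,
    "skip_5p_nt": 21,
    "min_mean_cov": 40.0,
    # demand floor for codons never observed in the weighted transcriptome
    "ncu_zero_floor": 1e-6,
}


@dataclass
class RunManifest:
    """Identity of a run: inputs, seed, conventions, config hash."""

    seed: int
    config_hash: str
    version: str
    options: dict[str, Any]
    inputs: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "codonopt_version": self.version,
            "options": self.options,
            "inputs": self.inputs,
        }


@dataclass
class ResultBundle:
    manifest: RunManifest
    tac: TAcVector
    cu: CodonUsageVector
    ncu: CodonUsageVector
    optimality: OptimalityTable
    pause: PauseTable | None
    te: pd.Series | None
    offsets: dict[int, int]
    reports: dict[str, dict]  # correlation reports keyed by comparison name

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.tac.to_tsv(out / "tac.tsv")
        self.cu.to_tsv(out / "genomic_cu.tsv")
        self.ncu.to_tsv(out / "ncu.tsv")
        self.optimality.write(out, self.tac, self.ncu)
        if self.pause is not None:
            self.pause.to_tsv(out)
        if self.te is not None:
            self.te.rename("log2_te").rename_axis("gene_id").to_csv(
                out / "translation_efficiency.tsv", sep="\t"
            )
        (out / "psite_offsets.json").write_text(
            json.dumps({str(k): v for k, v in sorted(self.offsets.items())}, indent=2)
        )
        (out / "reports.json").write_text(json.dumps(self.reports, indent=2))
        (out / "manifest.json").write_text(json.dumps(self.manifest.to_dict(), indent=2))


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def _spearman_report(x: pd.Series, y: pd.Series) -> dict:
    from scipy import stats

    shared = x.index.intersection(y.index)
    rho, p = stats.spearmanr(x.loc[shared], y.loc[shared])
    return {"rho": float(rho), "p_value": float(p), "n": int(len(shared))}


def run_pipeline(
    config: dict | str | Path, seed: int | None = None, out_dir: str | Path | None = None
) -> ResultBundle:
    """Execute the full analysis from a config mapping or YAML path.

    Config keys: ``simulate`` (bool), ``simulation`` (SimulationConfig
    fields), ``inputs`` (paths: cds_fasta, trna_counts, rna_counts,
    ribo_reads), ``options`` (stage options, see module defaults),
    ``seed``. ``seed``/``out_dir`` arguments override the config.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text()) or {}
    config = dict(config)
    if seed is not None:
        config["seed"] = seed
    run_seed = int(config.get("seed", 0))
    options = {**_DEFAULT_OPTIONS, **config.get("options", {})}
    simulate = bool(config.get("simulate", False))

    ribo_reads_df: pd.DataFrame | None = None
    gene_lengths: dict[str, int] = {}
    ribo_gene_counts: dict[str, float] | None = None

    if simulate:
        sim_kwargs = dict(config.get("simulation", {}))
        sim = SimulationConfig(seed=run_seed, **sim_kwargs)
        rng = sim.rng()
        trna_table, _ = simulate_trna_pool(sim, rng)
        transcripts, expr, _ = simulate_transcriptome(sim, rng)
        ribo_reads_df, _ = simulate_ribo_profile(transcripts, sim, rng)
        # simulated footprint depth is deliberately sparse; the deep-data
        # coverage filter would empty it unless the config asks otherwise
        if "min_mean_cov" not in config.get("options", {}):
            options["min_mean_cov"] = 0.0
        inputs = {"mode": "simulated"}
    else:
        paths = config.get("inputs", {})
        required = ["cds_fasta", "trna_counts", "rna_counts"]
        missing = [k for k in required if k not in paths or not Path(paths[k]).exists()]
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")
        transcripts = TranscriptSet.from_fasta(paths["cds_fasta"])
        trna_table = AnticodonCountTable.from_tsv(paths["trna_counts"])
        expr = ExpressionTable.from_tsv(paths["rna_counts"], options["pseudocount"])
        if "ribo_reads" in paths and Path(paths["ribo_reads"]).exists():
            ribo_reads_df = pd.read_csv(paths["ribo_reads"], sep="\t", comment="#")
        inputs = {k: str(v) for k, v in paths.items()}

    gene_lengths = {g: len(s) // 3 for g, s in transcripts}

    # --- tRNA pool -> TAc -------------------------------------------------
    abundance = normalize_trna_counts(trna_table, options["pseudocount"])
    penalties = (
        WobblePenaltySet.from_yaml(config["penalties_yaml"])
        if "penalties_yaml" in config
        else WobblePenaltySet.default()
    )
    tac = compute_tac(abundance, penalties=penalties, isotype=trna_table.isotype)
    logger.info("TAc computed over %d codons", len(tac.codon_space))

    # --- codon usage, demand weighting, optimality -----------------------
    counts = count_codons(transcripts)
    cu = genomic_codon_usage(counts)
    ncu = abundance_weighted_usage(counts, expr)
    opt = OptimalityTable.compute(
        counts,
        tac,
        ncu,
        length_normalize=options["length_normalize"],
        zero_floor=options["ncu_zero_floor"],
    )
    bins = bin_by_abundance(expr, n_bins=min(options["n_bins"], max(2, len(expr.gene_ids))))
    logger.info(
        "optimality: %d low outliers, %d high outliers",
        len(opt.outliers_low), len(opt.outliers_high),
    )

    # --- ribosome profiling ----------------------------------------------
    pause: PauseTable | None = None
    te: pd.Series | None = None
    offsets: dict[int, int] = {}
    if ribo_reads_df is not None and not ribo_reads_df.empty:
        raw_profile = RiboProfile.from_read_table(ribo_reads_df, gene_lengths)
        psite = metagene_psite_offsets(raw_profile)
        offsets = psite.offsets
        profile = assign_asite_density(raw_profile, psite, options["a_site_shift"])
        profile = filter_genes(
            profile,
            min_len_nt=options["min_len_nt"],
            skip_5p_nt=options["skip_5p_nt"],
            min_mean_cov=options["min_mean_cov"],
        )
        if profile.per_gene_density:
            pause = pause_scores(
                profile,
                transcripts,
                genomic_mean=options["genomic_mean"],
                fg_interior=options["fg_interior"],
            )
        ribo_gene_counts = (
            ribo_reads_df.groupby("gene_id")["count"].sum().astype(float).to_dict()
        )
        te = translation_efficiency(
            ribo_gene_counts, expr.raw.to_dict(), options["pseudocount"]
        )

    # --- comparison reports ----------------------------------------------
    reports: dict[str, dict] = {
        "tac_vs_genomic_cu": _spearman_report(tac.TAc, cu.relative),
        "ncu_vs_genomic_cu": _spearman_report(ncu.relative, cu.relative),
        "mopt_vs_abundance": _spearman_report(opt.mOpt, expr.a),
        "abundance_bins": {"n_bins": bins.n_bins, "sizes": [len(b) for b in bins]},
    }
    if te is not None:
        reports["mopt_vs_te"] = _spearman_report(opt.mOpt, te)
    if pause is not None:
        reports["pause_vs_tac"] = _spearman_report(pause.genomic, tac.TAc)

    manifest = RunManifest(
        seed=run_seed,
        config_hash=_config_hash(config),
        version=__version__,
        options={k: v for k, v in options.items() if not k.startswith("setdefault")},
        inputs=inputs,
    )
    bundle = ResultBundle(
        manifest=manifest,
        tac=tac,
        cu=cu,
        ncu=ncu,
        optimality=opt,
        pause=pause,
        te=te,
        offsets=offsets,
        reports=reports,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
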