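"""Gene filtering, metagene offsets, pause scores, and TE ratios."""

import numpy as np
import pandas as pd
import pytest

from codonopt import (
    RiboProfile,
    SimulationConfig,
    TranscriptSet,
    amino_acid_pause,
    assign_asite_density,
    filter_genes,
    metagene_psite_offsets,
    pause_scores,
    simulate_ribo_profile,
    simulate_transcriptome,
    translation_efficiency,
)


def uniform_profile(gene_id: str, n_codons: int, per_nt: float) -> RiboProfile:
    return RiboProfile(
        gene_lengths_codons={gene_id: n_codons},
        per_gene_density={gene_id: np.full(3 * n_codons, per_nt)},
    )


class TestFilterGenes:
    def test_short_gene_removed_regardless_of_coverage(self):
        prof = uniform_profile("g1", 30, 1000.0)  # 90 nt
        assert filter_genes(prof).gene_ids == []

    def test_boundary_coverage_retained(self):
        prof = uniform_profile("g1", 100, 40.0)  # 300 nt, exactly 40 reads/nt
        assert filter_genes(prof).gene_ids == ["g1"]

    def test_leading_coverage_only_removed(self):
        dens = np.zeros(300)
        dens[:21] = 1000.0
        prof = RiboProfile(
            gene_lengths_codons={"g1": 100}, per_gene_density={"g1": dens}
        )
        assert filter_genes(prof).gene_ids == []

    def test_skip_region_excluded_from_mean(self):
        dens = np.zeros(300)
        dens[21:] = 50.0
        prof = RiboProfile(
            gene_lengths_codons={"g1": 100}, per_gene_density={"g1": dens}
        )
        assert filter_genes(prof).gene_ids == ["g1"]


class TestMetageneOffsets:
    def _single_peak_profile(self, offset: int, rlen: int, n_reads: int) -> RiboProfile:
        return RiboProfile(
            gene_lengths_codons={"g1": 100},
            read_5p_positions={("g1", rlen): np.full(n_reads, -offset)},
        )

    def test_single_peak_recovery(self):
        prof = self._single_peak_profile(offset=14, rlen=30, n_reads=60)
        res = metagene_psite_offsets(prof)
        assert res.offsets == {30: 14}

    def test_per_length_peaks(self):
        prof = RiboProfile(
            gene_lengths_codons={"g1": 100},
            read_5p_positions={
                ("g1", 28): np.full(80, -12),
                ("g1", 29): np.full(80, -13),
            },
        )
        res = metagene_psite_offsets(prof)
        assert res.offsets == {28: 12, 29: 13}

    def test_deep_gene_does_not_dominate(self):
        """Per-gene normalization: one gene with 10x reads contributes the
        same unit mass as every other gene."""
        genes = {f"g{i}": 100 for i in range(5)}
        reads = {}
        for i in range(5):
            n = 500 if i == 0 else 50
            pos = np.concatenate([np.full(n, -13), np.array([7, 22, 40])])
            reads[(f"g{i}", 30)] = pos
        prof = RiboProfile(gene_lengths_codons=genes, read_5p_positions=reads)
        res = metagene_psite_offsets(prof)
        meta = res.metagene[30]
        assert meta.sum() == pytest.approx(5.0)  # one unit per gene
        assert res.offsets[30] == 13

    def test_absent_length_has_no_offset(self):
        prof = self._single_peak_profile(offset=14, rlen=30, n_reads=10)
        res = metagene_psite_offsets(prof)
        assert 31 not in res.offsets

    def test_generator_truth_recovered_for_every_length(self):
        cfg = SimulationConfig(seed=3, n_genes=200, reads_per_gene_mean=80.0)
        rng = cfg.rng()
        ts, _, _ = simulate_transcriptome(cfg, rng)
        _, prof = simulate_ribo_profile(ts, cfg, rng)
        # every length must carry enough reads for the check to be meaningful
        for rlen in range(26, 36):
            n = sum(len(v) for (g, rl), v in prof.read_5p_positions.items() if rl == rlen)
            assert n >= 50
        res = metagene_psite_offsets(prof)
        assert res.offsets == cfg.psite_offsets_truth


class TestAsiteAssignment:
    def test_read_maps_to_asite(self):
        prof = RiboProfile(
            gene_lengths_codons={"g1": 10},
            read_5p_positions={("g1", 30): np.array([3 - 16, 6 - 16])},
        )
        out = assign_asite_density(prof, {30: 13}, a_site_shift=3)
        dens = out.per_gene_density["g1"]
        assert dens[3] == 1 and dens[6] == 1 and dens.sum() == 2

    def test_psite_mode(self):
        prof = RiboProfile(
            gene_lengths_codons={"g1": 10},
            read_5p_positions={("g1", 30): np.array([-13])},
        )
        out = assign_asite_density(prof, {30: 13}, a_site_shift=0)
        assert out.per_gene_density["g1"][0] == 1


class TestPauseScores:
    def test_uniform_density_literal_formula(self):
        """Uniform coverage scores (L-2)/L at every interior codon — the
        literal normalization keeps the full-vector sum in F_g."""
        L = 100
        ts = TranscriptSet(records=[("g1", "ATG" + "GCG" * (L - 2) + "TAA")])
        prof = uniform_profile("g1", L, 2.0)
        table = pause_scores(prof, ts)
        expected = (L - 2) / L
        assert np.allclose(table.positional["score"].to_numpy(), expected)

    def test_interior_only_variant_scores_one(self):
        L = 100
        ts = TranscriptSet(records=[("g1", "ATG" + "GCG" * (L - 2) + "TAA")])
        dens = np.zeros(3 * L)
        dens[3 : 3 * (L - 1)] = 2.0
        prof = RiboProfile(gene_lengths_codons={"g1": L}, per_gene_density={"g1": dens})
        table = pause_scores(prof, ts, fg_interior=True)
        assert np.allclose(table.positional["score"].to_numpy(), 1.0)

    def test_single_loaded_codon(self):
        L = 50
        ts = TranscriptSet(records=[("g1", "ATG" + "GCG" * (L - 2) + "TAA")])
        dens = np.zeros(3 * L)
        dens[3 * 10] = 600.0
        prof = RiboProfile(gene_lengths_codons={"g1": L}, per_gene_density={"g1": dens})
        table = pause_scores(prof, ts)
        pos = table.positional.set_index("codon_index")["score"]
        assert pos[10] == pytest.approx(L - 2)
        assert pos.drop(10).abs().max() == 0.0

    def test_scale_invariance(self, rng):
        L = 60
        ts = TranscriptSet(records=[("g1", "ATG" + "GACGTC" * ((L - 2) // 2) + "TAA")])
        dens = rng.poisson(5.0, size=3 * L).astype(float)
        p1 = RiboProfile(gene_lengths_codons={"g1": L}, per_gene_density={"g1": dens})
        p2 = RiboProfile(gene_lengths_codons={"g1": L}, per_gene_density={"g1": dens * 7.5})
        t1 = pause_scores(p1, ts)
        t2 = pause_scores(p2, ts)
        assert np.allclose(
            t1.positional["score"].to_numpy(), t2.positional["score"].to_numpy()
        )

    def test_vectorized_matches_bruteforce(self, rng):
        """Naive per-codon recomputation agrees exactly on random profiles."""
        cfg = SimulationConfig(seed=17, n_genes=20, gene_length_range=(100, 300))
        ts, _, _ = simulate_transcriptome(cfg)
        lengths = {g: len(s) // 3 for g, s in ts}
        density = {
            g: rng.poisson(3.0, size=3 * L).astype(float) for g, L in lengths.items()
        }
        prof = RiboProfile(gene_lengths_codons=lengths, per_gene_density=density)
        table = pause_scores(prof, ts)
        seqs = dict(ts.records)
        scores = {
            (r.gene_id, r.codon_index): r.score for r in table.positional.itertuples()
        }
        for g, L in lengths.items():
            R = density[g]
            fg = R.sum() / (L - 2)
            for i in range(1, L - 1):
                manual = R[3 * i : 3 * i + 3].sum() / fg
                assert scores[(g, i)] == pytest.approx(manual, abs=0, rel=0)
        # genomic score is the pooled positional mean
        df = table.positional
        for codon, grp in df.groupby("codon"):
            assert table.genomic[codon] == pytest.approx(grp["score"].mean())

    def test_first_and_last_codons_ignored(self):
        L = 10
        ts = TranscriptSet(records=[("g1", "ATG" + "GCG" * (L - 2) + "TAA")])
        prof = uniform_profile("g1", L, 1.0)
        table = pause_scores(prof, ts)
        idx = set(table.positional["codon_index"])
        assert idx == set(range(1, L - 1))

    def test_programmed_dwell_recovered(self):
        """A 5x dwell on AGA appears as ~5x the median genomic pause."""
        cfg = SimulationConfig(seed=11, n_genes=400, pause_multipliers={"AGA": 5.0})
        rng = cfg.rng()
        ts, _, _ = simulate_transcriptome(cfg, rng)
        _, prof = simulate_ribo_profile(ts, cfg, rng)
        offs = metagene_psite_offsets(prof)
        table = pause_scores(assign_asite_density(prof, offs), ts)
        ratio = table.genomic["AGA"] / table.genomic.drop("AGA").median()
        assert ratio == pytest.approx(5.0, rel=0.10)


class TestAminoAcidPause:
    def test_singleton_family(self):
        genomic = pd.Series({"TGG": 2.5, "GAC": 1.0, "GAT": 3.0})
        aa = amino_acid_pause(genomic)
        assert aa["W"] == pytest.approx(2.5)

    def test_two_codon_family_mean(self):
        genomic = pd.Series({"GAC": 1.0, "GAT": 3.0})
        aa = amino_acid_pause(genomic)
        assert aa["D"] == pytest.approx(2.0)

    def test_missing_codon_mean_over_observed(self):
        genomic = pd.Series({"GGC": 2.0, "GGA": 4.0})  # Gly family of 4, 2 observed
        aa = amino_acid_pause(genomic)
        assert aa["G"] == pytest.approx(3.0)


class TestTranslationEfficiency:
    def test_identity_tables_give_zero(self):
        counts = {"g1": 10, "g2": 200, "g3": 3000}
        te = translation_efficiency(counts, counts, pseudocount=0.0)
        assert np.allclose(te.to_numpy(), 0.0)

    def test_doubled_gene_oracle(self):
        """Doubling one gene's ribo count shifts every TE by the CPM
        renormalization; the oracle recomputes from first principles."""
        rna = {"g1": 100.0, "g2": 300.0, "g3": 600.0}
        ribo = {"g1": 200.0, "g2": 300.0, "g3": 600.0}
        te = translation_efficiency(ribo, rna, pseudocount=0.0)
        for g in rna:
            ribo_cpm = ribo[g] / sum(ribo.values()) * 1e6
            rna_cpm = rna[g] / sum(rna.values()) * 1e6
            assert te[g] == pytest.approx(np.log2(ribo_cpm / rna_cpm))

    def test_scale_invariance(self, rng):
        rna = {f"g{i}": float(c) for i, c in enumerate(rng.integers(10, 5000, 50))}
        ribo = {f"g{i}": float(c) for i, c in enumerate(rng.integers(10, 5000, 50))}
        t1 = translation_efficiency(ribo, rna)
        t2 = translation_efficiency(
            {g: 3 * v for g, v in ribo.items()}, {g: 11 * v for g, v in rna.items()}
        )
        assert np.allclose(t1.to_numpy(), t2.to_numpy())

    def test_empty_overlap_is_error(self):
        with pytest.raises(ValueError, match="shared"):
            translation_efficiency({"a": 1}, {"b": 1})
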