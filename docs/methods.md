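# Methods

## Scope and model

`codonopt` scores how well each codon, and each mRNA, is matched to a
cell's measured tRNA pool, and asks whether that match is visible in
ribosome behavior. It is built for genomes with single-copy tRNA genes
(the motivating case is *M. tuberculosis* H37Rv), where gene-copy-number
proxies for tRNA abundance are uninformative and the pool must be
sequenced.

The chain of quantities is:

1. **tRNA abundance.** Per-anticodon read counts (one gene per
   anticodon) are scaled to counts-per-million within each replicate,
   averaged across replicates, and log2-transformed with a pseudocount:
   `abundance = log2(mean CPM + pc)`. CPM-per-replicate-then-mean makes
   replicates of unequal depth commensurable; the raw-count and
   pseudocount choices are configurable. Anticodons with zero reads are
   retained (they flow into the zero-adaptiveness fallback below)
   rather than dropped.
2. **Decoding map and TAc.** A codon 5'-c1c2c3-3' is decodable by an
   anticodon 5'-a34a35a36-3' when c1:a36 and c2:a35 pair Watson–Crick
   and c3:a34 pairs Watson–Crick or by an allowed wobble. Position-34
   modifications are applied first: every A34 anticodon is treated as
   inosine (decoding U-, C-, and A-ending codons) and the Ile-isotype
   CAT anticodon as lysidine (decoding ATA); both rules and the codon
   space are editable in `data/wobble_penalties.yaml`. The pairing
   penalties default to the published dos Reis (2004) tAI constants —
   G:U 0.41, U:G 0.68, I:C 0.28, I:A 0.9999, lysidine:A 0.89, 0 for
   Watson–Crick — bundled in the same user-overridable file. These
   constants were fitted to *S. cerevisiae* data and their transfer to
   other species is an assumption, not a measurement.
   Absolute adaptiveness is `W_i = Σ_j (1 − s_ij)·abundance_j`;
   relative adaptability is `TAc_i = W_i / W_max`, and codons with
   `W_i = 0` receive the geometric mean of the non-zero relative
   values (computed on normalized values, the original tAI
   convention). TAc is computed over the 60 sense codons minus ATG;
   stop codons are always excluded, and a 61-codon space is available
   for generic use. With the bundled full anticodon set every codon
   has at least one decoder, so the fallback only triggers on partial
   pools.
3. **Usage and demand.** Genomic usage `cu_i = Σ_j C_ij / N` counts
   frame-0 codons of annotated CDS (start codons included by default;
   switchable). Demand-weighted usage multiplies each gene's counts by
   its abundance weight `a_j = log2(CPM_j + 1)`; the RNA-seq
   normalization is deliberately simple because `a_j` enters only
   through relative weights. Genes present in only one of the CDS and
   expression tables are dropped from the join with a logged count.
4. **Optimality.** `cOpt_i = log2(TAc_i / nCU_i)`; codons the weighted
   transcriptome never uses have no defined demand and require an
   explicit floor (the pipeline defaults to 1e-6 with a warning).
   Per-mRNA optimality is the length-normalized mean,
   `mOpt_raw_j = Σ_i C_ij·cOpt_i / Σ_i C_ij`, scaled by
   `max_j |mOpt_raw_j|` so that higher remains more optimal. The
   length-normalized mean was chosen because an unnormalized sum
   scales with gene length and cannot produce a narrow, comparable
   per-mRNA score band; the literal raw sum is available with
   `length_normalize=False`, and the convention in force is recorded
   in the run manifest. Outliers are fenced at Q1 − 1.5·IQR and
   Q3 + 1.5·IQR with linear-interpolation (type-7) quartiles —
   documented because outlier counts are sensitive to the quartile
   convention; values strictly beyond the fences are flagged.
5. **Ribosome profiling.** Genes shorter than 100 nt, or with mean
   coverage below 40 reads/nt computed after skipping the first 21 nt,
   are removed (both thresholds inclusive; the skip avoids initiation
   inflation). P-site offsets are estimated per read length (26–35 nt)
   from a metagene over the half-open window [−50, +200) around the
   start codon: each gene's 5'-end count vector is normalized to sum 1
   before summation so deep genes cannot dominate, and the offset is
   the distance from the metagene peak to the start. The stated window
   "−50 to +200" spans 251 positions but a 250-length vector; the
   half-open reading resolves the off-by-one. A-site density places
   each read at 5'-end + offset + 3 nt (offsets are P-site quantities;
   `a_site_shift=0` gives P-site scoring). Pause scores use the
   literal normalization `F_g = sum(R_g)/(L_g − 2)` over the full
   density vector, which makes uniform coverage score (L−2)/L rather
   than 1; an interior-only variant (`fg_interior=True`) scores
   uniform coverage as exactly 1. First and last codons are never
   scored. A codon's genomic pause score pools all positional scores
   across genes (default); a mean-of-per-gene-means variant is
   available, and per-amino-acid scores are unweighted means over the
   observed synonymous codons. Translation efficiency is a plain
   log2(footprint CPM / mRNA CPM) ratio — a density proxy that models
   no count overdispersion and is not comparable to model-based TE
   estimators.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of the study inputs with
known ground truth: a single-copy pool of 43 distinct anticodons whose
true abundances are log-uniform over a configurable fold-range
(default 10×, the order-of-magnitude spread such pools show), with two
multinomial replicates at 1M reads; transcriptomes of 400 genes of
100–300 codons drawn codon-by-codon from a configurable bias (uniform
by default) with log-normal expression (sd 2 log2 units) and one
multinomial RNA-seq draw at 5M reads; and footprints with
Poisson(50)-per-gene depth, triangular read lengths peaking at 30 nt,
per-length P-site offsets of 11–15 nt, codon dwell multipliers
(default 1), and a 5% initiation-peak component (ribosomes with the P
site on the start codon) that gives the metagene estimator its peak.
The bundled anticodon table is a reconstruction of the standard H37Rv
complement and is labelled a synthetic stand-in.

Not emulated: sequence-content biases of library preparation, tRNA
modification-induced misincorporation, rRNA contamination, positional
(5' ramp) effects, operon structure, or any coupling between codon
content and expression unless explicitly programmed. Passing tests
therefore demonstrate that the estimators recover what the generator
planted under clean sampling noise — not that the biological
conclusions transfer to any particular real dataset.

Default problem sizes (400 genes, 50 reads/gene, 1M-read tRNA
replicates) were chosen as the smallest sizes at which the planted
effects are comfortably identifiable; the deep-data coverage filter
(40 reads/nt) is skipped by the pipeline in simulate mode because
synthetic footprint depth is deliberately sparse, and any configured
value overrides this.

## Numerical and design choices

- All randomness flows from one `numpy.random.Generator` seeded in the
  config; identical manifests reproduce byte-identical outputs.
- Ties in abundance binning are broken by gene id, making bin
  membership deterministic; bins differ in size by at most one.
- The rank test between abundance bins is two-sided Mann–Whitney
  without continuity correction, and degenerate all-tied comparisons
  report p = 1 rather than NaN. No multiple-testing correction is
  applied (single-codon tests).
- The geometric-mean fallback, the mOpt scaling convention, the F_g
  variant, and the A-site shift are all recorded in the run manifest
  so downstream consumers can tell which conventions produced a table.
- Empty decoder lists, all-zero pools, zero-coverage genes, frame
  breaks, and empty joins raise informative errors rather than
  propagating NaNs; ambiguous-base CDS records are rejected per record
  with a logged id.

## Known limitations

- The wobble penalty constants are species-agnostic defaults; no
  species-specific refitting is provided.
- Aminoacylation levels and modification stoichiometry are outside the
  model: "abundance" is read counts, not charged-tRNA availability.
- The TE ratio is a labelled non-equivalent stand-in for model-based
  translation-efficiency estimation.
- Isoform-free, prokaryotic single-CDS gene models are assumed;
  minus-strand coverage must be reverse-complemented upstream of the
  per-gene density interface.
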