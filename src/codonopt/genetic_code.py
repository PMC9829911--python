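"""Genetic-code bookkeeping shared by every module.

The standard (NCBI table 1) code is used throughout; Mycobacterium
tuberculosis and other bacteria covered by this pipeline translate with
the standard table. Codons are DNA-alphabet, uppercase, 5'->3'.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, stop codons excluded
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: all 61 sense codons, lexicographic
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: the default analysis space: 61 sense codons minus ATG (Met is decoded
#: by a dedicated initiator/elongator system and is conventionally left
#: out of tRNA-adaptation analyses), giving 60 codons.
CODON_SPACE_60: tuple[str, ...] = tuple(c for c in SENSE_CODONS if c != "ATG")

#: generic 61-codon space for non-tAI uses
CODON_SPACE_61: tuple[str, ...] = SENSE_CODONS

COMPLEMENT: dict[str, str] = {"A": "T", "C": "G", "G": "C", "T": "A"}


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def amino_acid(codon: str) -> str:
    """One-letter amino acid for a sense codon; '*' for a stop codon."""
    return CODON_TO_AA.get(codon, "*")


def synonymous_families(codon_space: tuple[str, ...] = CODON_SPACE_60) -> dict[str, list[str]]:
    """Map amino acid -> codons of that amino acid within ``codon_space``."""
    fams: dict[str, list[str]] = {}
    for codon in codon_space:
        fams.setdefault(CODON_TO_AA[codon], []).append(codon)
    return fams


def wc_anticodon(codon: str) -> str:
    """The Watson-Crick anticodon (5'->3') pairing a codon at all three positions."""
    return reverse_complement(codon)
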