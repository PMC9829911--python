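"""Codon->decoder enumeration under wobble rules and tRNA adaptability (TAc).

The adaptiveness of codon *i* to a measured tRNA pool is

    W_i = sum_j (1 - s_ij) * tRNC_j

over the n_i isoacceptors that can decode the codon, where tRNC_j is
the (log2 CPM) abundance of decoder j and s_ij a selective constraint
in [0, 1]: 0 for Watson-Crick pairing at the third position, larger
for wobble pairs, near 1 for the inosine:A pair. Relative adaptability
is piecewise:

    TAc_i = W_i / W_max          if W_i != 0
    TAc_i = W_mean               otherwise,

with W_mean the geometric mean of the non-zero relative values — codons
the pool cannot decode are given a middling, non-zero score rather
than zero (the convention of the original tRNA adaptation index).

Decoding geometry: a codon 5'-c1 c2 c3-3' pairs an anticodon written
5'-a34 a35 a36-3' antiparallel, so c1:a36 and c2:a35 must be
Watson-Crick and c3:a34 may be Watson-Crick or an allowed wobble after
applying position-34 modification rules (A34 -> inosine; C34 of the
bacterial Ile2 decoder -> lysidine).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genetic_code import CODON_SPACE_60, COMPLEMENT, amino_acid
from .trna_quant import TrnaAbundance

_VALID_BASES = frozenset("ACGT")


def _load_default_config() -> dict:
    ref = importlib.resources.files("codonopt.data") / "wobble_penalties.yaml"
    return yaml.safe_load(ref.read_text())


@dataclass
class WobblePenaltySet:
    """Pairing constraints s(base34:codon3) plus position-34 modification rules."""

    penalties: dict[str, float]  # "X:Y" -> s, X = effective base34, Y = codon 3rd base
    a34_inosine: bool = True
    lysidine_ile_cat: bool = True

    def __post_init__(self) -> None:
        for pair, s in self.penalties.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"penalty {pair} = {s} outside [0, 1]")
        # Watson-Crick pairs must carry no penalty
        for b34, c3 in (("G", "C"), ("C", "G"), ("T", "A"), ("A", "T")):
            s = self.penalties.get(f"{b34}:{c3}")
            if s is not None and s != 0.0:
                raise ValueError(f"Watson-Crick pair {b34}:{c3} must have s = 0")

    @classmethod
    def default(cls) -> "WobblePenaltySet":
        cfg = _load_default_config()
        rules = cfg.get("modification_rules", {})
        return cls(
            penalties=dict(cfg["penalties"]),
            a34_inosine=bool(rules.get("a34_inosine", True)),
            lysidine_ile_cat=bool(rules.get("lysidine_ile_cat", True)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WobblePenaltySet":
        cfg = yaml.safe_load(Path(path).read_text())
        rules = cfg.get("modification_rules", {})
        return cls(
            penalties=dict(cfg["penalties"]),
            a34_inosine=bool(rules.get("a34_inosine", True)),
            lysidine_ile_cat=bool(rules.get("lysidine_ile_cat", True)),
        )

    def effective_base34(self, anticodon: str, isotype: str | None = None) -> str:
        """Base at position 34 after modification (I = inosine, L = lysidine)."""
        b34 = anticodon[0]
        if self.lysidine_ile_cat and anticodon == "CAT" and isotype in ("I", "Ile"):
            return "L"
        if self.a34_inosine and b34 == "A":
            return "I"
        return b34

    def wobble_penalty(self, effective_b34: str, codon3: str) -> float | None:
        """s for the third-position pair, or None if the pair is disallowed."""
        return self.penalties.get(f"{effective_b34}:{codon3}")


@dataclass
class DecodingMap:
    """codon -> list of (anticodon, s) decoders; n_i = list length."""

    decoders: dict[str, list[tuple[str, float]]]
    codon_space: tuple[str, ...]

    def n_decoders(self, codon: str) -> int:
        return len(self.decoders[codon])


def build_decoding_map(
    anticodons: Sequence[str],
    penalties: WobblePenaltySet | None = None,
    codon_space: Sequence[str] = CODON_SPACE_60,
    isotype: Mapping[str, str] | None = None,
) -> DecodingMap:
    """Enumerate, per codon, the anticodons that can decode it and their s.

    Positions 1-2 of the codon must pair Watson-Crick with anticodon
    positions 36-35; position 3 pairs position 34 by Watson-Crick or an
    allowed wobble after modification rules. ``isotype`` (anticodon ->
    amino acid) is only needed to identify the lysidine-modified Ile
    CAT decoder among CAT anticodons.
    """
    penalties = penalties or WobblePenaltySet.default()
    isotype = isotype or {}
    for ac in anticodons:
        if len(ac) != 3 or not set(ac) <= _VALID_BASES:
            raise ValueError(f"invalid anticodon {ac!r}")
    decoders: dict[str, list[tuple[str, float]]] = {c: [] for c in codon_space}
    for codon in codon_space:
        c1, c2, c3 = codon
        for ac in anticodons:
            if ac[2] != COMPLEMENT[c1] or ac[1] != COMPLEMENT[c2]:
                continue
            b34 = penalties.effective_base34(ac, isotype.get(ac))
            s = penalties.wobble_penalty(b34, c3)
            if s is not None:
                decoders[codon].append((ac, s))
    return DecodingMap(decoders=decoders, codon_space=tuple(codon_space))


@dataclass
class TAcVector:
    """Absolute (W) and relative (TAc) adaptiveness per codon."""

    W: pd.Series
    TAc: pd.Series
    W_max: float
    W_mean: float  # geometric mean of non-zero relative values (the fallback)
    n_decoders: pd.Series | None = None

    @property
    def codon_space(self) -> tuple[str, ...]:
        return tuple(self.TAc.index)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "codon": self.TAc.index,
                "amino_acid": [amino_acid(c) for c in self.TAc.index],
                "n_decoders": (
                    self.n_decoders.reindex(self.TAc.index).to_numpy()
                    if self.n_decoders is not None
                    else -1
                ),
                "W": self.W.reindex(self.TAc.index).to_numpy(),
                "TAc": self.TAc.to_numpy(),
            }
        )
        df.to_csv(path, sep="\t", index=False)


def absolute_adaptiveness(decoding_map: DecodingMap, abundance: TrnaAbundance) -> pd.Series:
    """W_i = sum over decoders j of (1 - s_ij) * abundance_j.

    Codons with no decoder get W_i = 0. Every anticodon appearing in
    the map must have an abundance entry.
    """
    W = {}
    for codon in decoding_map.codon_space:
        total = 0.0
        for ac, s in decoding_map.decoders[codon]:
            if ac not in abundance.abundance.index:
                raise KeyError(f"no abundance entry for anticodon {ac}")
            total += (1.0 - s) * abundance[ac]
        W[codon] = total
    return pd.Series(W, index=list(decoding_map.codon_space), dtype=float)


def normalize_tac(W: pd.Series, n_decoders: pd.Series | None = None) -> TAcVector:
    """Normalize W to the maximum; geometric-mean fallback for W_i = 0."""
    if (W == 0).all():
        raise ValueError("all W values are zero: the pool decodes nothing")
    w_max = float(W.max())
    rel = W / w_max
    nonzero = rel[W != 0]
    w_mean = float(np.exp(np.mean(np.log(nonzero))))
    tac = rel.where(W != 0, w_mean)
    return TAcVector(W=W, TAc=tac, W_max=w_max, W_mean=w_mean, n_decoders=n_decoders)


def compute_tac(
    abundance: TrnaAbundance,
    anticodons: Sequence[str] | None = None,
    penalties: WobblePenaltySet | None = None,
    codon_space: Sequence[str] = CODON_SPACE_60,
    isotype: Mapping[str, str] | None = None,
) -> TAcVector:
    """Convenience composition: decoding map -> W -> TAc.

    ``anticodons`` defaults to the anticodons present in ``abundance``.
    """
    if anticodons is None:
        anticodons = list(abundance.abundance.index)
    dmap = build_decoding_map(anticodons, penalties, codon_space, isotype)
    W = absolute_adaptiveness(dmap, abundance)
    n_dec = pd.Series(
        {c: dmap.n_decoders(c) for c in dmap.codon_space}, dtype=int
    )
    return normalize_tac(W, n_decoders=n_dec)


def gene_copy_abundance(anticodons: Sequence[str]) -> TrnaAbundance:
    """Unit abundance per anticodon — the gene-copy-number mode for a
    single-copy genome, where wobble penalties alone shape W."""
    ab = pd.Series(1.0, index=list(dict.fromkeys(anticodons)))
    return TrnaAbundance(abundance=ab, normalization_label="gene copy number")


def load_bundled_anticodons() -> pd.DataFrame:
    """The bundled single-copy anticodon set (columns: anticodon,
    amino_acid, isotype) standing in for the Mtb H37Rv annotation."""
    ref = importlib.resources.files("codonopt.data") / "anticodons_mtb.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")
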