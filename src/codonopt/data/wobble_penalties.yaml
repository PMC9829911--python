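# Wobble-pairing selective constraints s(base34 : codon-3rd-base).
# Watson-Crick pairs carry s = 0; non-WC pairs carry the published
# tAI constants of dos Reis et al. (2004). "I" is inosine (deaminated
# A34), "L" is lysidine (modified C34 of the bacterial Ile2 decoder).
# Any pair not listed is disallowed (the anticodon does not decode
# codons ending in that base).
penalties:
  "G:C": 0.0      # Watson-Crick
  "C:G": 0.0      # Watson-Crick
  "T:A": 0.0      # Watson-Crick
  "A:T": 0.0      # Watson-Crick (unmodified A34, rare)
  "G:T": 0.41     # G34 : U3 wobble
  "T:G": 0.68     # U34 : G3 wobble
  "I:T": 0.0      # inosine : U
  "I:C": 0.28     # inosine : C
  "I:A": 0.9999   # inosine : A — near-total penalty
  "L:A": 0.89     # lysidine : A (bacterial Ile ATA decoding)

# Effective base at anticodon position 34 after modification.
# a34: blanket rule by wobble base; anticodon/isotype entries override.
modification_rules:
  a34_inosine: true          # every A34 anticodon is treated as inosine-modified
  lysidine_ile_cat: true     # the Ile-isotype CAT anticodon is lysidine-modified
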