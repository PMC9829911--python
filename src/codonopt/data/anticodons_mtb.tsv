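# Synthetic stand-in for the M. tuberculosis H37Rv tRNA gene complement
# (single-copy tRNA genes), reconstructed from the public H37Rv tRNA
# annotation. One row per distinct anticodon; the Met/fMet CAT decoders
# are omitted because ATG lies outside the 60-codon analysis space, so
# CAT here is the lysidine-modified Ile2 decoder. anticodon is 5'->3' DNA.
anticodon	amino_acid	isotype
CGC	A	Ala
GGC	A	Ala
TGC	A	Ala
ACG	R	Arg
CCG	R	Arg
CCT	R	Arg
TCT	R	Arg
GTT	N	Asn
GTC	D	Asp
GCA	C	Cys
CTG	Q	Gln
TTG	Q	Gln
CTC	E	Glu
TTC	E	Glu
CCC	G	Gly
GCC	G	Gly
TCC	G	Gly
GTG	H	His
GAT	I	Ile
CAT	I	Ile
CAA	L	Leu
CAG	L	Leu
GAG	L	Leu
TAA	L	Leu
TAG	L	Leu
CTT	K	Lys
TTT	K	Lys
GAA	F	Phe
CGG	P	Pro
GGG	P	Pro
TGG	P	Pro
CGA	S	Ser
GCT	S	Ser
GGA	S	Ser
TGA	S	Ser
CGT	T	Thr
GGT	T	Thr
TGT	T	Thr
CCA	W	Trp
GTA	Y	Tyr
CAC	V	Val
GAC	V	Val
TAC	V	Val
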