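# Default inverse PPR code: which (5th, last) residue pair to use when
# programming a motif of a given type against a given RNA base.
# These are package defaults following the commonly used code
# (TN->A, TD->G, ND->U, NS->C) applied uniformly to all P/L/S motif types;
# edit this file to use a different code.
motif_type	nucleotide	fifth	last
P1	A	T	N
P1	C	N	S
P1	G	T	D
P1	U	N	D
L1	A	T	N
L1	C	N	S
L1	G	T	D
L1	U	N	D
S1	A	T	N
S1	C	N	S
S1	G	T	D
S1	U	N	D
P2	A	T	N
P2	C	N	S
P2	G	T	D
P2	U	N	D
L2	A	T	N
L2	C	N	S
L2	G	T	D
L2	U	N	D
S2	A	T	N
S2	C	N	S
S2	G	T	D
S2	U	N	D
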