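# Default binding-preference scores per (5th, last) residue pair and RNA base.
# Positive = favoured, 0 = neutral, negative = disfavoured.  These are
# package defaults consistent with the shipped code table (the preferred base
# of each code entry scores highest); replace with an empirically derived
# table for real analyses.  Pairs absent from this file score the table's
# default (0, neutral).
fifth	last	A	C	G	U
T	N	1.0	0.0	0.25	0.25
T	D	0.25	0.0	1.0	0.0
S	N	1.0	0.1	0.3	0.3
S	D	0.2	0.0	1.0	0.0
N	D	0.0	0.4	0.0	1.0
N	S	0.2	1.0	0.0	0.6
N	N	0.1	0.5	0.0	0.5
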