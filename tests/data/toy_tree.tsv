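gene_id	f1	f2	f3	label
g1	1	1	0	active
g2	1	0	1	active
g3	1	1	1	active
g4	0	1	0	active
g5	0	0	1	inactive
g6	1	0	0	inactive
g7	0	0	1	inactive
g8	0	1	0	inactive
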