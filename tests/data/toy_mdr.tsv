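gene_id	a	b	label
g01	1	1	active
g02	1	1	active
g03	1	0	active
g04	1	0	active
g05	0	1	active
g06	1	1	active
g07	0	0	inactive
g08	0	1	inactive
g09	0	0	inactive
g10	1	0	inactive
g11	0	0	inactive
g12	0	1	inactive
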