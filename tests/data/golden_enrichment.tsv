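gene_set	t1	t2	t3
S1	1.0	0.0	0.0
S2	1.0	0.5	0.0
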