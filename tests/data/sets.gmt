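S1	first_set	g1	g2
S2	second_set	g1	g3	gX
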