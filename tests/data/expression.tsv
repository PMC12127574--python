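gene_id	n1	n2	t1	t2	t3
g1	1.0	3.0	4.0	3.0	1.0
g2	5.0	5.0	6.0	5.0	2.0
g3	2.0	4.0	10.0	5.0	0.0
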