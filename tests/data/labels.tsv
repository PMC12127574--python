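n1	normal
n2	normal
t1	tumor
t2	tumor
t3	tumor
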