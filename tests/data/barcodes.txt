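n1
n2
t1
t2
t3
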