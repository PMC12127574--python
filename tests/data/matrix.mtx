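%%MatrixMarket matrix coordinate real general
3 5 15
1 1 1.0
1 2 3.0
1 3 4.0
1 4 3.0
1 5 1.0
2 1 5.0
2 2 5.0
2 3 6.0
2 4 5.0
2 5 2.0
3 1 2.0
3 2 4.0
3 3 10.0
3 4 5.0
3 5 0.0
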