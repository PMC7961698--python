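%MatrixMarket matrix coordinate integer general
3 2 5
1 1 5
2 1 3
3 1 1
1 2 2
3 2 7
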