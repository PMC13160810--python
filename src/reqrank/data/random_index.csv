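n,ri
1,0.0
2,0.0
3,0.58
4,0.90
5,1.12
6,1.24
7,1.32
8,1.41
9,1.45
10,1.49
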