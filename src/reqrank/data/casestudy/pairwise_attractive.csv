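,N1,N2,N3,N4
N1,1,1/2,1/3,1
N2,2,1,1/2,1/4
N3,3,2,1,1/2
N4,1,4,2,1
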