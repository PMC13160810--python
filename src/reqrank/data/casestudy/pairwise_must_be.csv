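,M1,M2,M3,M4,M5,M6,M7
M1,1,1/2,1,1/2,1,1,1/2
M2,2,1,1/2,1,1/3,1/2,1
M3,1,2,1,1,1,1,1/2
M4,2,1,2,2,1/2,2,1
M5,1,3,1,2,1,1,1
M6,1,2,1,1,1,1,1/2
M7,2,1,2,1,1,1,1
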