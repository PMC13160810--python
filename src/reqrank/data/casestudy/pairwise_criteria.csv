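,M,O,A
M,1,1/2,1
O,1,1,2
A,1,1/2,1
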