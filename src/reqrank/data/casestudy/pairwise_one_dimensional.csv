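,O1,O2,O3,O4,O5
O1,1,1/3,1/2,1,1/2
O2,3,1,1,1/3,1
O3,2,1,1,1,1/2
O4,1,1,1,1,1
O5,2,2,2,1,1
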