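alternative,M1,M2,M3,M4,M5,O1,O2,O3,O4,O5,N1,N2,N3,N4,N5
design_scheme,5.6,3.6,5.1,3.2,4.5,4.7,3.9,5.1,5.6,4.9,3.7,4.6,5.2,4.8,4.3
evaluation_sample,5.8,2.9,4.6,4.7,5.1,2.7,4.5,4.1,3.8,3.6,4.6,4.2,3.8,5.1,4.7
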