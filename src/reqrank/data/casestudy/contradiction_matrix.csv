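improving,worsening,principles
34,36,36;26;12;17
43,37,25;13;28;2;10;7
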