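id,name
34,Practicality (age-friendly)
36,System complexity
37,System security
43,Automation level
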