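matrix,lambda_max,ci,cr
must_be,8.552,0.079,0.056
one_dimensional,5.425,0.106,0.095
attractive,5.441,0.110,0.098
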