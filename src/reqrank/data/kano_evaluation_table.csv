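functional,like,must_be,neutral,live_with,dislike
like,Q,A,A,A,O
must_be,R,I,I,I,M
neutral,R,I,I,I,M
live_with,R,I,I,I,M
dislike,R,R,R,R,Q
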