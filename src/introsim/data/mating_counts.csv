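line,n_cages,n_ss,n_si,n_is,n_ii
78P,2,38,19,34,29
6H,3,44,39,40,23
62P,2,32,32,27,29
29P,2,24,20,46,30
94P,2,47,30,18,23
28H,4,58,46,74,61
12H,2,41,18,32,29
60H,3,47,38,52,43
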