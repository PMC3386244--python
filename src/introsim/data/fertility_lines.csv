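line,group,progeny_mean,progeny_se
sim132,wildtype,289,82.4
25H,introgression,,
78P,introgression,324,74.8
6H,introgression,313,58.8
62P,introgression,334,76.3
29P,introgression,329,39.7
94P,introgression,214,30.8
28H,introgression,211,65.6
12H,introgression,263,84.8
60H,introgression,339,36.4
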