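marker,h,c,s
A,0,0.1,0.7
A,0.5,0.2,0.5
A,0.9,0.4,0.5
A,1,0.3,0.4
B,0,0,0.5
B,0.5,0,0.3
B,0.9,0,0.2
B,1,0,0.2
C,0,0,0.9
C,0.5,0,0.4
C,0.9,0,0.3
C,1,0,0.2
D1,0,0.2,0.9
D1,0.5,0.5,0.9
D1,0.9,0.2,0.4
D1,1,0.2,0.4
D2,0,0,0.2
D2,0.5,0,0.4
D2,0.9,0,0.3
D2,1,0,0.6
E1,0,0,0.5
E1,0.5,0,0.6
E1,0.9,0,0.5
E1,1,0,0.5
E2,0,0,0.3
E2,0.5,0,0.2
E2,0.9,0,0.3
E2,1,0,0.3
F1,0,0,0.3
F1,0.5,0,0.2
F1,0.9,0,0.5
F1,1,0,0.5
F2,0,0,0.9
F2,0.5,0,0.3
F2,0.9,0,0.3
F2,1,0,0.2
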