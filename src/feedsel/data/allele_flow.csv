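class,B1,B2,B3,B4,B5,C1,C2,C3,C4,C5
B1,0,0.167,0.167,0.167,0,0,0.125,0.125,0.125,0.125
B2,1,0,0,0,0,0,0,0,0,0
B3,0,1,0,0,0,0,0,0,0,0
B4,0,0,1,0,0,0,0,0,0,0
B5,0,0,0,1,0,0,0,0,0,0
C1,0,0.117,0.117,0.192,0.075,0,0.125,0.125,0.125,0.125
C2,0,0,0,0,0,1,0,0,0,0
C3,0,0,0,0,0,0,1,0,0,0
C4,0,0,0,0,0,0,0,1,0,0
C5,0,0,0,0,0,0,0,0,1,0
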