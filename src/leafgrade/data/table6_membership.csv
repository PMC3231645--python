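class,U11,U12,U13,U21,U22,U23,U31,U32,U33
X1L,0.2,0.2,0.3,0.2,0.3,0.2,0.3,0.1,0.3
B4L,0.5,0.6,0.6,0.5,0.5,0.7,0.5,0.7,0.5
S1,0.3,0.2,0.1,0.3,0.2,0.1,0.2,0.2,0.2
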