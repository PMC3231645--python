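class,U11,U12,U13,U21,U22,U23,U31,U32,U33
X1L,2123,41937,0.011,0.48,-1.43,33.14,887,696,575
B4L,941,16478,0.036,0.71,-0.9,25.43,1027,826,593
S1,2069,41242,0.08,0.42,-1.53,35.57,633,612,523
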