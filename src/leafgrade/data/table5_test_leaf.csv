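U11,U12,U13,U21,U22,U23,U31,U32,U33
820,18236,0.038,0.72,-0.89,25.22,1032,853,698
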