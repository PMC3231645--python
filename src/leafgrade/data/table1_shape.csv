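no,surface_area_px,surface_perimeter_px,disfigurement_pct
1,40502,1080,1.28
2,48607,1308,0.56
3,39775,1013,3.96
4,57862,1406,3.01
5,18515,544,4.74
6,25924,956,1.90
7,10803,289,2.91
8,14435,419,3.12
9,59146,1750,2.16
10,30747,727,9.47
11,26838,625,1.47
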