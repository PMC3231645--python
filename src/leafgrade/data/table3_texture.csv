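no,energy,entropy,contrast
1,47.85714,145,33.14286
2,45,150.2857,35.42857
3,51,135.8333,33.33333
4,44,144.5714,32.42857
5,57.28571,121.5714,31.28572
6,54,126.8333,27.83333
7,35,172.1429,41
8,48,143.8571,34
9,35.33333,158.6667,33.33333
10,38.28571,163.7143,39.85714
11,44.85714,146.5714,34.28571
12,61.6,110.4,27.4
13,71.57143,89.28571,25.42857
14,40,149.3333,32.33333
15,61.28571,106.5714,26.71428
16,69.2,85.4,21.8
17,52.25,121.25,27
18,64.75,94,24
19,46.42857,128.2857,25.57143
20,53.42857,113.8571,25.42857
21,42.57143,152.2857,35.57143
22,42.28571,153,37.71429
23,55.28571,120.4286,29.28572
24,39.14286,157,35.14286
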