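no,var_r,var_g,var_b
1,185.4286,150.7143,95.14286
2,185.5714,153,98.57143
3,183,154.3333,103
4,157.2857,123.1429,76.14286
5,162,132,87.14286
6,175,144.1667,94.33334
7,163.8571,129.1429,81
8,174,141,90.42857
9,132,102.6667,66.33334
10,157.5714,122.5714,77.71429
11,160,127.2857,82
12,167.2,136.6,88.4
13,162.8571,135.5714,88.85714
14,130.1667,100.3333,65.16666
15,141,110.4286,73.42857
16,129.2,102.6,69.4
17,120.625,94.25,65.125
18,114.5,91.75,67
19,119.7143,94.71429,68.28571
20,111.5714,91.42857,68.14286
21,170.4286,138.2857,89.42857
22,150.2857,116.1429,72.28571
23,142.7143,113.4286,75.42857
24,160.7143,126.4286,77.28571
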