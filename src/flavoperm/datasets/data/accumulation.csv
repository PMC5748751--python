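id,ca_ab_mean,ca_ab_sd,ca_ba_mean,ca_ba_sd,ratio_c_printed,direction_diff
1,1.932,0.051,3.183,0.504,1.65,p<0.05
2,2.706,0.174,2.423,0.543,0.90,ns
3,1.038,0.212,1.586,0.045,1.53,ns
4,1.182,0.341,3.272,0.445,2.77,p<0.05
5,3.876,0.741,8.639,1.275,2.23,p<0.01
6,4.415,0.467,7.610,0.694,1.72,p<0.01
7,3.902,0.251,8.828,0.213,2.26,p<0.01
8,0.024,0.002,0.044,0.007,1.83,ns
9,3.780,0.711,9.286,0.859,2.46,p<0.01
10,NT,NT,NT,NT,-,unevaluable
11,0.129,0.008,0.060,0.011,0.464,p<0.01
12,8.368,1.039,11.887,1.247,1.42,p<0.05
13,2.746,0.478,0.496,0.249,0.18,p<0.01
14,ND,ND,ND,ND,-,unevaluable
15,0.332,0.066,0.076,0.048,0.23,p<0.05
16,ND,ND,ND,ND,-,unevaluable
17,ND,ND,ND,ND,-,unevaluable
18,1.293,0.086,1.644,0.300,1.27,ns
19,1.935,0.305,4.436,0.299,2.29,p<0.01
20,0.058,0.013,0.068,0.011,1.17,ns
21,0.635,0.146,1.234,0.249,1.94,p<0.05
22,ND,ND,ND,ND,-,unevaluable
23,3.819,1.320,4.842,0.424,1.27,ns
24,ND,ND,ND,ND,-,unevaluable
25,1.821,0.774,0.158,0.021,0.09,p<0.05
26,0.500,0.104,1.236,0.117,2.47,p<0.01
27,1.415,0.276,2.777,0.220,1.96,p<0.01
28,6.766,1.583,14.087,1.287,2.08,p<0.01
29,4.393,0.790,8.804,1.576,2.00,p<0.05
30,0.096,0.010,0.251,0.012,2.61,ns
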