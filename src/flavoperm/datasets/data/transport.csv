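id,papp_ab_mean,papp_ab_sd,papp_ba_mean,papp_ba_sd,ratio_p_printed
1,22.35,1.37,21.73,1.21,0.97
2,21.86,0.585,23.94,0.45,1.10
3,16.43,1.20,18.07,1.62,1.10
4,1.95,0.53,0.71,0.21,0.37
5,10.10,7.33,21.45,2.12,2.12
6,17.12,1.72,16.92,1.02,0.99
7,6.78,0.12,8.41,0.62,1.24
8,3.28,0.32,2.81,0.24,0.86
9,1.94,0.41,1.75,0.44,0.90
10,2.55,1.45,4.68,0.41,1.84
11,8.23,0.87,21.58,0.32,2.62
12,6.68,0.93,5.92,0.45,0.89
13,0.35,0.06,0.23,0.03,0.66
14,0.29,0.01,0.44,0.01,1.50
15,1.09,0.02,0.90,0.42,0.83
16,4.24,1.25,5.96,1.20,1.41
17,4.04,0.07,4.28,0.44,1.06
18,23.50,0.85,27.92,2.76,1.19
19,32.13,2.98,35.34,1.16,1.10
20,3.73,0.73,5.09,1.55,1.36
21,30.97,0.80,36.96,1.97,1.19
22,6.32,1.16,26.08,2.08,4.13
23,17.42,1.78,18.31,1.83,1.05
24,2.25,0.96,2.70,0.41,1.20
25,12.45,0.91,6.23,0.46,0.50
26,33.90,3.55,42.19,3.11,1.24
27,31.07,2.13,30.48,2.13,0.98
28,11.11,0.51,10.70,2.98,0.96
29,13.76,0.73,20.04,1.29,1.46
30,4.25,0.53,5.08,1.08,1.20
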