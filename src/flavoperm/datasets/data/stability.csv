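id,relative_concentration,recovery_ba_mean,recovery_ba_sd,rsd_ba,recovery_ab_mean,recovery_ab_sd,rsd_ab
1,60.10,-,-,-,-,-,-
2,12.09,-,-,-,-,-,-
3,51.64,-,-,-,-,-,-
4,34.12,-,-,-,-,-,-
5,87.51,-,-,-,-,-,-
6,41.76,-,-,-,-,-,-
7,47.63,-,-,-,-,-,-
8,72.75,61.83,0.72,1.16,72.31,18.76,25.96
9,105.96,-,-,-,-,-,-
10,52.10,-,-,-,-,-,-
11,79.06,90.12,1.39,1.56,81.45,6.70,8.22
12,98.60,-,-,-,-,-,-
13,7.25,-,-,-,-,-,-
14,ND,-,-,-,-,-,-
15,90.67,-,-,-,-,-,-
16,116.67,76.77,9.36,12.19,90.69,8.85,9.76
17,66.82,96.95,1.67,1.72,98.18,4.74,4.84
18,115.83,-,-,-,-,-,-
19,113.93,-,-,-,-,-,-
20,64.99,82.88,10.99,13.26,93.17,7.62,8.18
21,71.02,-,-,-,-,-,-
24,30.31,85.25,0.60,0.70,87.42,3.31,3.79
25,85.60,-,-,-,-,-,-
26,74.83,-,-,-,-,-,-
27,88.16,-,-,-,-,-,-
28,81.33,-,-,-,-,-,-
29,131.85,-,-,-,-,-,-
30,-,79.50,1.24,1.58,78.66,1.30,1.65
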