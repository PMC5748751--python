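id,ppapp_exp,ppapp_pred,split,QC3p,E_sol,SlogP_V3,vsurf_ID1
1,4.651,4.756,training,0.010,-0.789,0,0.736
2,4.660,4.947,training,-0.019,-1.802,0,4.097
3,4.784,4.803,training,0.011,1.526,0,1.561
5,4.820,4.663,training,0.305,-3.225,0,0.474
6,4.766,4.751,training,-0.007,-0.893,0,0.636
7,5.169,5.197,training,0.011,0.986,0,8.594
8,5.484,5.709,training,-0.004,-2.750,41.853,2.774
10,5.594,5.278,training,0.301,0.378,25.386,0.822
11,5.085,5.243,training,-0.033,0.104,25.386,0.359
15,5.962,5.322,training,0.322,1.610,25.386,1.034
16,5.373,5.041,training,0.272,-2.100,0,6.626
17,5.394,5.363,training,0.276,-10.491,20.927,8.232
18,4.629,4.750,training,-0.028,1.351,0,0.685
19,4.493,4.754,training,-0.018,-1.043,0,0.669
21,4.509,4.731,training,-0.019,-2.117,0,0.228
22,5.199,4.755,training,0.302,-0.789,0,1.064
23,4.759,4.735,training,-0.012,-1.910,0,0.334
24,5.648,5.370,training,-0.034,1.320,20.927,4.292
25,4.905,4.749,training,-0.023,-1.314,0,0.553
26,4.470,4.730,training,-0.023,-2.317,0,0.190
28,4.954,4.753,training,-0.006,0.600,0,0.690
29,4.861,4.765,training,-0.013,-1.601,0,0.861
9,5.712,5.347,test,0.005,3.668,25.386,2.195
12,5.175,5.254,test,0.005,2.066,25.386,0.548
14,6.535,5.376,test,0.295,3.979,25.386,1.045
20,5.429,5.514,test,-0.034,-6.238,20.927,6.492
27,4.508,4.745,test,-0.022,-0.205,0,0.527
30,5.372,5.062,test,0.291,-10.370,20.926,3.024
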