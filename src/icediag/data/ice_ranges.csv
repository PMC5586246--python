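bin,d_start,d_end
1,3.953,3.807
2,3.753,3.581
3,3.482,3.371
4,2.692,2.635
5,2.294,2.209
6,2.094,2.041
7,1.954,1.939
8,1.935,1.897
9,1.890,1.863
10,1.723,1.712
11,1.527,1.516
12,1.476,1.465
13,1.446,1.434
14,1.372,1.365
15,1.305,1.292
16,1.285,1.247
17,1.240,1.217
18,1.186,1.162
19,1.136,1.119
20,1.099,1.067
21,1.052,1.029
22,1.017,1.011
23,1.000,0.984
24,0.981,0.975
25,0.973,0.966
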