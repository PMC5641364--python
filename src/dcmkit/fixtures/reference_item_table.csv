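item,selected,discrimination,sx2_stat,sx2_df,sx2_p,dif_sex_stat,dif_sex_df,dif_sex_p,dif_region_stat,dif_region_df,dif_region_p
1,ACDM,0.597,164.60,137,0.054,0.00,8,1.00,4.88,8,0.77
2,ACDM,0.562,148.81,138,0.25,0.04,4,1.00,1.82,4,0.77
3,GDINA,0.560,167.17,139,0.052,0.00,2,1.00,0.24,2,0.89
4,GDINA,0.578,151.87,139,0.215,0.00,2,1.00,0.04,2,0.98
5,ACDM,0.545,144.11,138,0.344,0.00,4,1.00,2.58,4,0.63
6,ACDM,0.563,173.71,137,0.019,0.00,8,1.00,6.47,8,0.60
7,LLM,0.544,155.55,138,0.146,0.00,4,1.00,4.78,4,0.31
8,GDINA,0.513,164.32,139,0.07,0.02,2,0.99,0.11,2,0.95
9,GDINA,0.463,166.15,139,0.058,0.00,2,1.00,0.12,2,0.94
10,GDINA,0.564,145.50,139,0.336,0.03,2,0.99,0.22,2,0.90
11,ACDM,0.567,155.15,138,0.151,0.00,4,1.00,1.73,4,0.79
12,GDINA,0.516,135.98,139,0.557,0.01,2,0.99,0.07,2,0.97
13,RRUM,0.507,152.78,138,0.184,0.00,4,1.00,1.27,4,0.87
14,GDINA,0.530,166.22,139,0.057,0.00,2,1.00,0.16,2,0.92
15,GDINA,0.517,154.36,139,0.176,0.02,2,0.99,0.87,2,0.65
16,LLM,0.528,162.60,138,0.075,0.00,4,1.00,5.04,4,0.28
17,GDINA,0.598,152.26,139,0.209,0.00,2,1.00,0.16,2,0.92
18,GDINA,0.577,152.82,139,0.2,0.00,2,1.00,0.04,2,0.98
19,GDINA,0.570,134.97,139,0.581,0.00,2,1.00,0.08,2,0.96
20,GDINA,0.560,171.56,139,0.032,0.00,2,1.00,0.02,2,0.99
21,GDINA,0.616,171.87,139,0.03,0.00,2,1.00,0.08,2,0.96
22,RRUM,0.452,174.72,138,0.019,0.00,4,1.00,0.16,4,1.00
23,GDINA,0.610,140.34,139,0.452,0.01,2,1.00,0.26,2,0.88
24,GDINA,0.457,141.02,139,0.436,0.00,2,1.00,0.14,2,0.93
25,GDINA,0.584,118.76,139,0.892,0.00,2,1.00,0.29,2,0.87
26,GDINA,0.575,146.74,139,0.31,0.01,2,1.00,0.00,2,1.00
27,RRUM,0.594,164.89,138,0.059,0.02,4,1.00,0.61,4,0.96
28,GDINA,0.497,180.71,139,0.01,0.00,2,1.00,1.16,2,0.56
29,GDINA,0.598,137.23,139,0.526,0.01,2,0.99,0.08,2,0.96
30,LLM,0.589,163.66,138,0.067,0.02,4,1.00,2.03,4,0.73
31,GDINA,0.556,125.27,139,0.792,0.00,2,1.00,0.03,2,0.99
32,GDINA,0.568,146.82,139,0.308,0.00,2,1.00,0.42,2,0.81
33,GDINA,0.536,140.87,139,0.44,0.00,2,1.00,1.30,2,0.52
34,GDINA,0.603,162.37,139,0.085,0.01,2,1.00,1.01,2,0.60
35,GDINA,0.580,161.98,139,0.089,0.00,2,1.00,0.76,2,0.69
36,DINO,0.452,161.34,139,0.094,0.00,4,1.00,0.60,4,0.96
37,LLM,0.526,172.28,138,0.025,0.00,4,1.00,0.76,4,0.94
38,GDINA,0.554,104.15,139,0.988,0.00,2,1.00,0.06,2,0.97
39,GDINA,0.459,135.43,139,0.57,0.00,2,1.00,0.52,2,0.77
40,LLM,0.607,143.94,138,0.347,0.00,4,1.00,0.46,4,0.98
41,GDINA,0.542,161.09,139,0.097,0.00,2,1.00,0.96,2,0.62
42,GDINA,0.526,132.47,139,0.64,0.00,2,1.00,0.03,2,0.98
43,LLM,0.525,162.81,138,0.073,0.00,4,1.00,5.92,4,0.21
44,GDINA,0.585,175.30,139,0.02,0.00,2,1.00,0.08,2,0.96
45,GDINA,0.635,179.10,139,0.012,0.00,2,1.00,0.06,2,0.97
46,GDINA,0.642,171.92,139,0.03,0.00,2,1.00,0.03,2,0.98
47,GDINA,0.508,145.39,139,0.338,0.01,2,1.00,0.03,2,0.99
48,GDINA,0.576,161.88,139,0.09,0.01,2,1.00,0.14,2,0.93
49,GDINA,0.505,170.26,139,0.037,0.00,2,1.00,0.20,2,0.90
50,ACDM,0.502,150.20,138,0.226,0.01,4,1.00,0.42,4,0.98
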