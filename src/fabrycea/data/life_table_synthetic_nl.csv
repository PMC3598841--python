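age,sex,qx
0,male,0.004227
0,female,0.003664
1,male,0.001434
1,female,0.00122
2,male,0.000595
2,female,0.000485
3,male,0.000345
3,female,0.000264
4,male,0.000272
4,female,0.000199
5,male,0.000253
5,female,0.000181
6,male,0.00025
6,female,0.000178
7,male,0.000253
7,female,0.000178
8,male,0.000257
8,female,0.000181
9,male,0.000262
9,female,0.000184
10,male,0.000268
10,female,0.000187
11,male,0.000275
11,female,0.000191
12,male,0.000282
12,female,0.000195
13,male,0.00029
13,female,0.000199
14,male,0.000299
14,female,0.000204
15,male,0.000309
15,female,0.00021
16,male,0.00032
16,female,0.000216
17,male,0.000331
17,female,0.000223
18,male,0.000344
18,female,0.00023
19,male,0.000358
19,female,0.000238
20,male,0.000373
20,female,0.000247
21,male,0.00039
21,female,0.000257
22,male,0.000409
22,female,0.000268
23,male,0.000429
23,female,0.00028
24,male,0.000452
24,female,0.000294
25,male,0.000476
25,female,0.000308
26,male,0.000503
26,female,0.000324
27,male,0.000533
27,female,0.000342
28,male,0.000565
28,female,0.000362
29,male,0.000601
29,female,0.000383
30,male,0.00064
30,female,0.000407
31,male,0.000682
31,female,0.000433
32,male,0.000729
32,female,0.000462
33,male,0.000781
33,female,0.000494
34,male,0.000838
34,female,0.000529
35,male,0.0009
35,female,0.000567
36,male,0.000968
36,female,0.00061
37,male,0.001043
37,female,0.000657
38,male,0.001125
38,female,0.000708
39,male,0.001215
39,female,0.000765
40,male,0.001314
40,female,0.000828
41,male,0.001423
41,female,0.000897
42,male,0.001542
42,female,0.000973
43,male,0.001673
43,female,0.001057
44,male,0.001816
44,female,0.001149
45,male,0.001974
45,female,0.001251
46,male,0.002147
46,female,0.001363
47,male,0.002336
47,female,0.001487
48,male,0.002545
48,female,0.001623
49,male,0.002773
49,female,0.001773
50,male,0.003024
50,female,0.001938
51,male,0.003299
51,female,0.002121
52,male,0.003601
52,female,0.002321
53,male,0.003933
53,female,0.002542
54,male,0.004296
54,female,0.002786
55,male,0.004696
55,female,0.003055
56,male,0.005134
56,female,0.00335
57,male,0.005615
57,female,0.003676
58,male,0.006142
58,female,0.004036
59,male,0.006721
59,female,0.004431
60,male,0.007357
60,female,0.004868
61,male,0.008054
61,female,0.005348
62,male,0.00882
62,female,0.005878
63,male,0.00966
63,female,0.006461
64,male,0.010582
64,female,0.007104
65,male,0.011594
65,female,0.007812
66,male,0.012704
66,female,0.008593
67,male,0.013923
67,female,0.009453
68,male,0.015261
68,female,0.0104
69,male,0.016728
69,female,0.011444
70,male,0.018339
70,female,0.012595
71,male,0.020107
71,female,0.013862
72,male,0.022047
72,female,0.015259
73,male,0.024177
73,female,0.016798
74,male,0.026513
74,female,0.018494
75,male,0.029078
75,female,0.020363
76,male,0.031893
76,female,0.022421
77,male,0.034981
77,female,0.02469
78,male,0.038371
78,female,0.02719
79,male,0.042091
79,female,0.029944
80,male,0.046174
80,female,0.032979
81,male,0.050655
81,female,0.036323
82,male,0.055572
82,female,0.040007
83,male,0.060969
83,female,0.044067
84,male,0.066892
84,female,0.04854
85,male,0.073392
85,female,0.053469
86,male,0.080525
86,female,0.058901
87,male,0.088354
87,female,0.064885
88,male,0.096945
88,female,0.071479
89,male,0.106374
89,female,0.078745
90,male,0.116722
90,female,0.08675
91,male,0.128079
91,female,0.095571
92,male,0.140542
92,female,0.105291
93,male,0.15422
93,female,0.116001
94,male,0.169231
94,female,0.127801
95,male,0.185705
95,female,0.140804
96,male,0.203785
96,female,0.155131
97,male,0.223626
97,female,0.170917
98,male,0.245402
98,female,0.188312
99,male,0.2693
99,female,0.207478
100,male,0.295527
100,female,0.228597
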