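var_id,mean_case,sd_case,mean_control,sd_control
1,32.453112,4.867967,32.453112,4.867967
2,1.140315,0.171047,1.140315,0.171047
3,28.491833,4.273775,28.491833,4.273775
4,9.673982,1.451097,9.673982,1.451097
5,0.850699,0.127605,0.850699,0.127605
6,4.684126,0.702619,4.684126,0.702619
7,13.677546,2.051632,13.677546,2.051632
8,2.194976,0.329246,2.194976,0.329246
9,2.478345,0.371752,2.478345,0.371752
10,32.515442,4.877316,32.515442,4.877316
11,0.947142,0.142071,0.947142,0.142071
12,5.640232,0.846035,5.640232,0.846035
13,10.575754,1.586363,10.575754,1.586363
14,18.416482,2.762472,18.416482,2.762472
15,24.78521,3.717782,24.78521,3.717782
16,7.745458,1.161819,7.745458,1.161819
17,0.510095,0.076514,0.510095,0.076514
18,21.95,3.63,30.95,4.0
19,7.678742,1.151811,7.678742,1.151811
20,6.527365,0.979105,6.527365,0.979105
21,1.743072,0.261461,1.743072,0.261461
22,0.585674,0.087851,0.585674,0.087851
23,7.276723,1.091508,7.276723,1.091508
24,3.28,1.16,5.09,1.16
25,23.546448,3.531967,23.546448,3.531967
26,0.619078,0.092862,0.619078,0.092862
27,25.651337,3.847701,25.651337,3.847701
28,0.866126,0.129919,0.866126,0.129919
29,8.766957,1.315043,8.766957,1.315043
30,4.564724,0.684709,4.564724,0.684709
31,1.176485,0.176473,1.176485,0.176473
32,10.908533,1.63628,10.908533,1.63628
33,0.603472,0.090521,0.603472,0.090521
34,0.7,0.26,1.21,0.22
35,0.84,0.28,1.29,0.23
36,45.627987,6.844198,45.627987,6.844198
37,1.73632,0.260448,1.73632,0.260448
38,91.99,16.9,64.44,6.58
39,2.873105,0.430966,2.873105,0.430966
40,25.1949,3.779235,25.1949,3.779235
41,7.62,0.6,6.18,0.6
42,30.58,5.63,20.56,1.95
43,17.92,3.83,11.85,1.35
44,17.76,3.24,13.05,1.49
45,4.742099,0.711315,4.742099,0.711315
46,2.829821,0.424473,2.829821,0.424473
47,8.477398,1.27161,8.477398,1.27161
48,5.875452,0.881318,5.875452,0.881318
49,0.685528,0.102829,0.685528,0.102829
50,17.82217,2.673325,17.82217,2.673325
51,14.45,2.19,10.2,1.06
52,5.84,1.1,3.65,0.5
53,1.998879,0.299832,1.998879,0.299832
54,116.37,30.4,69.27,8.54
55,0.7,0.32,1.94,0.41
56,16.580602,2.48709,16.580602,2.48709
57,0.646753,0.097013,0.646753,0.097013
58,7.809838,1.171476,7.809838,1.171476
59,5.613275,0.841991,5.613275,0.841991
60,0.636859,0.095529,0.636859,0.095529
61,0.950533,0.14258,0.950533,0.14258
62,33.569793,5.035469,33.569793,5.035469
63,2.28,0.47,3.05,0.39
64,32.781536,4.91723,32.781536,4.91723
65,3.085248,0.462787,3.085248,0.462787
66,2.984887,0.447733,2.984887,0.447733
67,0.533051,0.079958,0.533051,0.079958
68,13.648261,2.047239,13.648261,2.047239
69,17.348958,2.602344,17.348958,2.602344
70,28.162667,4.2244,28.162667,4.2244
71,3.666365,0.549955,3.666365,0.549955
72,3.794241,0.569136,3.794241,0.569136
73,40.251441,6.037716,40.251441,6.037716
74,10.46407,1.569611,10.46407,1.569611
75,11.221198,1.68318,11.221198,1.68318
76,5.486315,0.822947,5.486315,0.822947
77,1.574054,0.236108,1.574054,0.236108
78,32.362407,4.854361,32.362407,4.854361
79,1.463684,0.219553,1.463684,0.219553
80,0.768288,0.115243,0.768288,0.115243
81,1.781494,0.267224,1.781494,0.267224
82,2.159139,0.323871,2.159139,0.323871
83,6.788294,1.018244,6.788294,1.018244
84,1.08624,0.162936,1.08624,0.162936
85,1.019234,0.152885,1.019234,0.152885
86,1.544316,0.231647,1.544316,0.231647
87,1.730728,0.259609,1.730728,0.259609
88,5.172996,0.775949,5.172996,0.775949
89,1.187779,0.178167,1.187779,0.178167
90,20.143507,3.021526,20.143507,3.021526
91,53.13,7.19,64.03,3.76
92,2.19861,0.329792,2.19861,0.329792
93,2.433819,0.365073,2.433819,0.365073
94,19.619963,2.942994,19.619963,2.942994
95,13.632412,2.044862,13.632412,2.044862
96,0.515384,0.077308,0.515384,0.077308
97,5.48458,0.822687,5.48458,0.822687
98,2.460823,0.369123,2.460823,0.369123
99,1.145276,0.171791,1.145276,0.171791
100,117.69,17.62,155.4,22.01
101,0.876842,0.131526,0.876842,0.131526
102,2.361311,0.354197,2.361311,0.354197
103,5.281555,0.792233,5.281555,0.792233
104,0.833623,0.125043,0.833623,0.125043
105,5.216637,0.782496,5.216637,0.782496
106,21.037407,3.155611,21.037407,3.155611
107,8.155989,1.223398,8.155989,1.223398
108,5.965179,0.894777,5.965179,0.894777
109,0.501256,0.075188,0.501256,0.075188
110,89.1,14.79,111.75,7.83
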