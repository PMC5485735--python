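var_id,ppm_hi,ppm_lo,assignment,is_glucose
1,8.6,8.4135,unassigned,False
2,8.4135,8.2271,unassigned,False
3,8.2271,8.0406,unassigned,False
4,8.0406,7.8541,unassigned,False
5,7.8541,7.6676,unassigned,False
6,7.6676,7.4812,unassigned,False
7,7.4812,7.2947,unassigned,False
8,7.2947,7.1082,unassigned,False
9,7.1082,6.9218,unassigned,False
10,6.9218,6.7353,unassigned,False
11,6.7353,6.5488,unassigned,False
12,6.5488,6.3624,unassigned,False
13,6.3624,6.1759,unassigned,False
14,6.1759,5.9894,unassigned,False
15,5.9894,5.8029,unassigned,False
16,5.8029,5.6165,unassigned,False
17,5.6165,5.43,unassigned,False
18,5.43,5.2752,-HC=CH- in fatty acid chain,False
19,5.2752,5.22,D-glucose (envelope),True
20,5.22,5.11,unassigned,False
21,5.11,5.0,unassigned,False
22,4.5,4.455,unassigned,False
23,4.455,4.41,unassigned,False
24,4.41,4.3159,C1H and C3H in glycerol backbone of triglycerides + OCH2 of choline in sphingomyelin/phosphatidylcholine,False
25,4.3159,4.2842,unassigned,False
26,4.2842,4.2526,unassigned,False
27,4.2526,4.2209,unassigned,False
28,4.2209,4.1893,unassigned,False
29,4.1893,4.1576,unassigned,False
30,4.1576,4.126,unassigned,False
31,4.126,4.0943,unassigned,False
32,4.0943,4.0627,unassigned,False
33,4.0627,4.031,unassigned,False
34,4.031,4.0136,L-serine,False
35,4.0136,4.001,L-serine,False
36,4.001,3.98,D-glucose (envelope),True
37,3.98,3.959,D-glucose (envelope),True
38,3.959,3.833,D-glucose,True
39,3.833,3.8143,unassigned,False
40,3.8143,3.7956,unassigned,False
41,3.7956,3.782,D-glucose,True
42,3.782,3.755,D-glucose,True
43,3.755,3.739,D-glucose,True
44,3.739,3.7141,D-glucose,True
45,3.7141,3.6937,unassigned,False
46,3.6937,3.6732,unassigned,False
47,3.6732,3.6528,unassigned,False
48,3.6528,3.6323,unassigned,False
49,3.6323,3.6119,unassigned,False
50,3.6119,3.5914,unassigned,False
51,3.5914,3.5649,D-glucose,True
52,3.5649,3.551,D-glucose,True
53,3.551,3.536,unassigned,False
54,3.536,3.398,D-glucose,True
55,3.398,3.3765,L-tryptophan,False
56,3.3765,3.3324,D-glucose (envelope),True
57,3.3324,3.2883,D-glucose (envelope),True
58,3.2883,3.2441,D-glucose (envelope),True
59,3.2441,3.2,D-glucose (envelope),True
60,3.2,3.1697,unassigned,False
61,3.1697,3.1393,unassigned,False
62,3.1393,3.109,unassigned,False
63,3.109,3.086,L-cysteine,False
64,3.086,3.0503,unassigned,False
65,3.0503,3.0147,unassigned,False
66,3.0147,2.979,unassigned,False
67,2.979,2.9433,unassigned,False
68,2.9433,2.9077,unassigned,False
69,2.9077,2.872,unassigned,False
70,2.872,2.8363,unassigned,False
71,2.8363,2.8007,unassigned,False
72,2.8007,2.765,unassigned,False
73,2.765,2.7293,unassigned,False
74,2.7293,2.6937,unassigned,False
75,2.6937,2.658,unassigned,False
76,2.658,2.6223,unassigned,False
77,2.6223,2.5867,unassigned,False
78,2.5867,2.551,unassigned,False
79,2.551,2.5153,unassigned,False
80,2.5153,2.4797,unassigned,False
81,2.4797,2.444,unassigned,False
82,2.444,2.4083,unassigned,False
83,2.4083,2.3727,unassigned,False
84,2.3727,2.337,unassigned,False
85,2.337,2.3013,unassigned,False
86,2.3013,2.2657,unassigned,False
87,2.2657,2.23,unassigned,False
88,2.23,2.1943,unassigned,False
89,2.1943,2.1587,unassigned,False
90,2.1587,2.123,unassigned,False
91,2.123,1.972,-CH2-CH=CH- in fatty acid chain,False
92,1.972,1.8936,unassigned,False
93,1.8936,1.8153,unassigned,False
94,1.8153,1.7369,unassigned,False
95,1.7369,1.6585,unassigned,False
96,1.6585,1.5801,unassigned,False
97,1.5801,1.5017,unassigned,False
98,1.5017,1.4234,unassigned,False
99,1.4234,1.345,unassigned,False
100,1.345,1.2458,CH3-(CH2)n- in fatty acid chain,False
101,1.2458,1.2147,unassigned,False
102,1.2147,1.1836,unassigned,False
103,1.1836,1.1525,unassigned,False
104,1.1525,1.1214,unassigned,False
105,1.1214,1.0904,unassigned,False
106,1.0904,1.0593,unassigned,False
107,1.0593,1.0282,unassigned,False
108,1.0282,0.9971,unassigned,False
109,0.9971,0.966,unassigned,False
110,0.966,0.8,CH3-(CH2)n- in fatty acid chain,False
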