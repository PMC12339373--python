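roi_index	roi_label	network
0	VN_1	VN
1	VN_2	VN
2	VN_3	VN
3	VN_4	VN
4	VN_5	VN
5	VN_6	VN
6	VN_7	VN
7	VN_8	VN
8	VN_9	VN
9	VN_10	VN
10	VN_11	VN
11	VN_12	VN
12	VN_13	VN
13	VN_14	VN
14	SMN_1	SMN
15	SMN_2	SMN
16	SMN_3	SMN
17	SMN_4	SMN
18	SMN_5	SMN
19	SMN_6	SMN
20	SMN_7	SMN
21	SMN_8	SMN
22	SMN_9	SMN
23	SMN_10	SMN
24	SMN_11	SMN
25	SMN_12	SMN
26	SMN_13	SMN
27	SMN_14	SMN
28	SMN_15	SMN
29	SMN_16	SMN
30	DAN_1	DAN
31	DAN_2	DAN
32	DAN_3	DAN
33	DAN_4	DAN
34	DAN_5	DAN
35	DAN_6	DAN
36	DAN_7	DAN
37	DAN_8	DAN
38	DAN_9	DAN
39	DAN_10	DAN
40	DAN_11	DAN
41	DAN_12	DAN
42	DAN_13	DAN
43	VAN_1	VAN
44	VAN_2	VAN
45	VAN_3	VAN
46	VAN_4	VAN
47	VAN_5	VAN
48	VAN_6	VAN
49	VAN_7	VAN
50	VAN_8	VAN
51	VAN_9	VAN
52	VAN_10	VAN
53	VAN_11	VAN
54	VAN_12	VAN
55	LN_1	LN
56	LN_2	LN
57	LN_3	LN
58	LN_4	LN
59	LN_5	LN
60	LN_6	LN
61	LN_7	LN
62	LN_8	LN
63	LN_9	LN
64	LN_10	LN
65	FPCN_1	FPCN
66	FPCN_2	FPCN
67	FPCN_3	FPCN
68	FPCN_4	FPCN
69	FPCN_5	FPCN
70	FPCN_6	FPCN
71	FPCN_7	FPCN
72	FPCN_8	FPCN
73	FPCN_9	FPCN
74	FPCN_10	FPCN
75	FPCN_11	FPCN
76	FPCN_12	FPCN
77	FPCN_13	FPCN
78	DMN_1	DMN
79	DMN_2	DMN
80	DMN_3	DMN
81	DMN_4	DMN
82	DMN_5	DMN
83	DMN_6	DMN
84	DMN_7	DMN
85	DMN_8	DMN
86	DMN_9	DMN
87	DMN_10	DMN
88	DMN_11	DMN
89	DMN_12	DMN
90	DMN_13	DMN
91	DMN_14	DMN
92	DMN_15	DMN
93	DMN_16	DMN
94	DMN_17	DMN
95	DMN_18	DMN
96	DMN_19	DMN
97	DMN_20	DMN
98	DMN_21	DMN
99	DMN_22	DMN
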