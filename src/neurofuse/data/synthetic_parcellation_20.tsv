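roi_index	roi_label	network
0	VN_1	VN
1	VN_2	VN
2	VN_3	VN
3	SMN_1	SMN
4	SMN_2	SMN
5	SMN_3	SMN
6	DAN_1	DAN
7	DAN_2	DAN
8	DAN_3	DAN
9	VAN_1	VAN
10	VAN_2	VAN
11	VAN_3	VAN
12	LN_1	LN
13	LN_2	LN
14	FPCN_1	FPCN
15	FPCN_2	FPCN
16	FPCN_3	FPCN
17	DMN_1	DMN
18	DMN_2	DMN
19	DMN_3	DMN
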