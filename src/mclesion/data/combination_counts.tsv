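combination	brain_wm	brain_ct1	brain_ct2	cb_wm	cb_gmwm	cb_gm
1	161	186	7	10	11	0
2	7	8	4	0	1	0
3	10	3	0	0	1	0
4	438	7	6	24	0	0
5	3	1	0	0	0	0
6	216	0	0	1	0	0
7	50	1	1	3	0	0
8	89	0	0	1	0	0
9	51	0	0	0	0	0
10	8	0	0	0	0	0
11	34	0	0	0	0	0
12	58	0	0	1	0	0
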