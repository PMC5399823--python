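code	NT1	NT2	NT3	NT4	NT5	T1	T2	T3	T4	T5
0010	7	8	7	8	7	9	7	8	8	8
0011	9	5	9	10	5	8	10	8	7	5
0101	142	142	142	142	142	142	142	142	142	142
1010	212	211	212	212	213	211	212	211	214	211
1011	1	2	1	1	2	2	1	2	2	2
1100	0	0	0	0	0	1	1	0	0	0
1111	67	67	67	67	68	67	67	66	68	67
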