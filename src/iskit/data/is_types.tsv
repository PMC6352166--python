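name	family	subgroup	min_len	max_len	dr_len	orf_count	motif	split_orf_tolerant
ISTth1	IS3	IS150	1200	1600	4	2	DDE	0
ISTth2	IS4	IS10	1200	1350	9	1	DDE	0
ISTth3	IS1634	IS4	1500	2000	6	1	unknown	0
ISTth4	IS256	-	1200	1500	9	1	DDE	0
ISTth5	IS256	-	1200	1500	0	1	DDE	0
ISTth6	IS630	-	1000	1400	2	1	DDE	0
ISTth7	IS5	ISH1	900	1150	8	1	DDE	1
ISTth8	IS701	-	1400	1550	4	1	DDE	0
IS1000A	IS110	-	1136	1558	2	1	DEDD	0
IS1000B	IS110	-	954	1558	0	1	DEDD	0
IS421	IS4	IS231	1450	5400	12	1	unknown	0
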