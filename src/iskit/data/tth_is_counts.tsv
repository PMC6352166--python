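strain	replicon	kind	length_bp	is_name	complete	partial
NAR1	NAR1_chr	chromosome	2021843	ISTth3	0	1
NAR1	NAR1_chr	chromosome	2021843	ISTth4	5	0
NAR1	NAR1_chr	chromosome	2021843	ISTth6	1	0
NAR1	NAR1_chr	chromosome	2021843	ISTth7	13	0
NAR1	NAR1_M1	megaplasmid	370865	ISTth1	1	0
NAR1	NAR1_M1	megaplasmid	370865	ISTth3	1	0
NAR1	NAR1_M1	megaplasmid	370865	ISTth4	11	0
NAR1	NAR1_M1	megaplasmid	370865	ISTth6	0	1
NAR1	NAR1_M1	megaplasmid	370865	ISTth7	5	0
NAR1	NAR1_M1	megaplasmid	370865	IS1000A/B	0	2
NAR1	NAR1_M2	megaplasmid	77135	ISTth7	0	2
HB27	HB27_chr	chromosome	1894877	ISTth2	2	0
HB27	HB27_chr	chromosome	1894877	ISTth3	2	1
HB27	HB27_chr	chromosome	1894877	ISTth5	1	0
HB27	HB27_chr	chromosome	1894877	ISTth6	3	0
HB27	HB27_chr	chromosome	1894877	ISTth7	2	2
HB27	HB27_chr	chromosome	1894877	ISTth8	3	0
HB27	HB27_chr	chromosome	1894877	IS1000A/B	1	8
HB27	HB27_pTT27	megaplasmid	232605	ISTth1	1	0
HB27	HB27_pTT27	megaplasmid	232605	ISTth2	1	0
HB27	HB27_pTT27	megaplasmid	232605	ISTth3	1	0
HB27	HB27_pTT27	megaplasmid	232605	ISTth5	1	0
HB27	HB27_pTT27	megaplasmid	232605	ISTth6	1	0
HB27	HB27_pTT27	megaplasmid	232605	ISTth7	4	1
HB27	HB27_pTT27	megaplasmid	232605	ISTth8	1	1
HB27	HB27_pTT27	megaplasmid	232605	IS1000A/B	1	34
HB8	HB8_chr	chromosome	1849742	ISTth4	4	0
HB8	HB8_chr	chromosome	1849742	ISTth6	1	0
HB8	HB8_chr	chromosome	1849742	ISTth7	6	2
HB8	HB8_chr	chromosome	1849742	IS1000A/B	1	14
HB8	HB8_pTT27	megaplasmid	256992	ISTth4	4	0
HB8	HB8_pTT27	megaplasmid	256992	ISTth6	1	1
HB8	HB8_pTT27	megaplasmid	256992	ISTth7	1	2
HB8	HB8_pTT27	megaplasmid	256992	ISTth8	2	0
HB8	HB8_pTT27	megaplasmid	256992	IS1000A/B	3	39
HB8	HB8_pVV8	plasmid	81151	ISTth1	1	0
HB8	HB8_pVV8	plasmid	81151	ISTth3	0	1
HB8	HB8_pVV8	plasmid	81151	ISTth4	2	0
HB8	HB8_pVV8	plasmid	81151	ISTth6	1	0
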