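label	locus	hr	ci_low	ci_high	p
chr2_18327703_18351537	2p24.2	1.28	0.85	1.94	0.239
chr10_13055619_13058458	10p13	1.67	1.05	2.66	0.031
chr6_29855945_29909559	6p22.1	1.24	0.99	1.56	0.057
chr9_73902148_73909871	9q21.12	1.55	1.07	2.25	0.021
chr8_8583109_8589783	8p23.1	1.87	1.02	3.43	0.042
chr13_34115595_34143545	13q13.2	1.43	1.07	1.91	0.015
chr20_36051525_42681088	20q11.23-20q13.12	0.65	0.40	1.05	0.079
chr6_31275246_31285292	6p21.33	1.27	0.92	1.74	0.150
chr1_161490896_161617516	1q23.3	1.17	0.72	1.90	0.520
chr6_77439969_77448731	6q14.1	1.35	1.04	1.74	0.023
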