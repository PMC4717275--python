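label	locus	cnv_type	size_kb	study	freq_pct	hr	ci_low	ci_high	p
chr2_18327703_18351537	2p24.2	DUP	23.8	DKLS	1.3	3.48	1.62	7.45	0.001
chr2_18327703_18351537	2p24.2	DUP	23.8	LLS	1.2	0.85	0.52	1.38	0.512
chr9_9516348_9526811	9p23	DUP	10.5	DKLS	1.0	3.30	1.45	7.53	0.005
chr9_9516348_9526811	9p23	DUP	10.5	LLS
chr13_32896846_32922331	13q13.1	DEL	25.5	DKLS	1.3	2.80	1.30	6.03	0.009
chr13_32896846_32922331	13q13.1	DEL	25.5	LLS
chr1_80982632_81056073	1p31.1	DUP	73.4	DKLS	1.0	2.97	1.29	6.80	0.010
chr1_80982632_81056073	1p31.1	DUP	73.4	LLS
chr6_55828727_55846527	6p12.1	DEL	17.8	DKLS	3.3	1.83	1.14	2.95	0.012
chr6_55828727_55846527	6p12.1	DEL	17.8	LLS
chr10_13055619_13058458	10p13	DEL	2.8	DKLS	2.0	2.08	1.17	3.72	0.013
chr10_13055619_13058458	10p13	DEL	2.8	LLS	1.2	1.15	0.53	2.47	0.729
chr6_29855945_29909559	6p22.1	DEL	53.6	DKLS	11.8	1.38	1.06	1.79	0.015
chr6_29855945_29909559	6p22.1	DEL	53.6	LLS	5.0	0.87	0.55	1.39	0.565
chr9_73902148_73909871	9q21.12	DUP	7.7	DKLS	1.8	2.05	1.12	3.75	0.020
chr9_73902148_73909871	9q21.12	DUP	7.7	LLS	4.0	1.31	0.81	2.10	0.272
chr8_8583109_8589783	8p23.1	DEL	6.7	DKLS	1.5	2.18	1.12	4.26	0.022
chr8_8583109_8589783	8p23.1	DEL	6.7	LLS	1.0	0.93	0.23	3.75	0.918
chr8_30990110_31000860	8p12	DEL	10.8	DKLS	1.0	2.60	1.14	5.94	0.023
chr8_30990110_31000860	8p12	DEL	10.8	LLS
chr13_34115595_34143545	13q13.2	DEL	28.0	DKLS	7.8	1.45	1.05	2.00	0.023
chr13_34115595_34143545	13q13.2	DEL	28.0	LLS	2.6	1.32	0.64	2.70	0.453
chr15_102028468_102305129	15q26.3	DUP	276.7	DKLS	1.0	2.52	1.12	5.69	0.026
chr15_102028468_102305129	15q26.3	DUP	276.7	LLS
chr20_36051525_42681088	20q11.23-20q13.12	DEL	6629.6	DKLS	1.8	0.45	0.22	0.91	0.026
chr20_36051525_42681088	20q11.23-20q13.12	DEL	6629.6	LLS	1.0	0.89	0.47	1.70	0.729
chr7_118006251_118070496	7q31.31	DEL	64.2	DKLS	1.0	2.69	1.11	6.56	0.029
chr7_118006251_118070496	7q31.31	DEL	64.2	LLS
chr6_31275246_31285292	6p21.33	DEL	10.0	DKLS	2.8	1.76	1.05	2.96	0.032
chr6_31275246_31285292	6p21.33	DEL	10.0	LLS	2.4	1.02	0.67	1.56	0.923
chr13_88960710_89033066	13q31.2	DEL	72.4	DKLS	1.0	2.38	1.06	5.37	0.036
chr13_88960710_89033066	13q31.2	DEL	72.4	LLS
chr22_18844632_19016663	22q11.21	DUP	172.0	DKLS	1.3	2.11	1.04	4.28	0.039
chr22_18844632_19016663	22q11.21	DUP	172.0	LLS
chr1_161490896_161617516	1q23.3	DUP	126.6	DKLS	1.8	0.48	0.23	0.98	0.043
chr1_161490896_161617516	1q23.3	DUP	126.6	LLS	1.4	2.60	1.35	5.04	0.004
chr6_77439969_77448731	6q14.1	DEL	8.8	DKLS	6.5	1.42	1.01	2.00	0.046
chr6_77439969_77448731	6q14.1	DEL	8.8	LLS	4.4	1.27	0.88	1.84	0.194
chr13_82081150_82087510	13q31.1	DEL	6.4	DKLS	1.0	2.28	1.01	5.14	0.048
chr13_82081150_82087510	13q31.1	DEL	6.4	LLS
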