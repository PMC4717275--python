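label	study	hr	ci_low	ci_high	p
number_all	DKLS	0.991	0.919	1.068	0.811
number_all	LLS	1.001	0.928	1.080	0.997
number_deletion	DKLS	1.049	0.957	1.150	0.307
number_deletion	LLS	1.163	0.959	1.409	0.124
number_duplication	DKLS	0.917	0.814	1.034	0.158
number_duplication	LLS	0.985	0.912	1.063	0.697
avg_length_all	DKLS	1.025	1.009	1.041	0.002
avg_length_all	LLS	1.012	0.963	1.062	0.644
avg_length_deletion	DKLS	1.015	1.002	1.027	0.023
avg_length_deletion	LLS	1.007	0.980	1.035	0.598
avg_length_duplication	DKLS	1.011	1.003	1.020	0.008
avg_length_duplication	LLS	1.009	0.977	1.042	0.597
total_length_all	DKLS	1.006	0.998	1.015	0.146
total_length_all	LLS	1.004	0.993	1.015	0.523
total_length_deletion	DKLS	1.011	1.000	1.023	0.050
total_length_deletion	LLS	1.009	1.004	1.014	0.001
total_length_duplication	DKLS	1.001	0.989	1.014	0.814
total_length_duplication	LLS	0.999	0.985	1.014	0.911
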