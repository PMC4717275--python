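label	hr	ci_low	ci_high	p
number_all	0.996	0.944	1.050	0.879
number_deletion	1.069	0.984	1.162	0.113
number_duplication	0.965	0.905	1.029	0.275
avg_length_all	1.024	1.009	1.039	0.002
avg_length_deletion	1.014	1.003	1.025	0.013
avg_length_duplication	1.011	1.003	1.019	0.005
total_length_all	1.005	0.999	1.012	0.107
total_length_deletion	1.009	1.004	1.015	0.0005
total_length_duplication	1.000	0.991	1.009	0.973
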