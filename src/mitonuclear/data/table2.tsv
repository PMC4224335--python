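# Per-mitonuclear-stratum counts, permutation p-values and published q-values
stratum	n_cases	n_total	proportion	p	q_smoother	q_bootstrap
HV_CC	183	265	0.691	0.006	0.016	0.015
HV_CG	184	236	0.780	0.413	0.128	0.117
HV_GG	27	38	0.711	0.557	0.138	0.127
IW_CC	67	82	0.817	0.230	0.105	0.096
IW_CG	54	81	0.667	0.063	0.057	0.052
IW_GG	9	10	0.900	0.469	0.128	0.117
JT_CC	94	118	0.797	0.318	0.124	0.114
JT_CG	52	68	0.765	0.887	0.202	0.185
JT_GG	17	20	0.850	0.439	0.128	0.117
UK_CC	206	284	0.725	0.200	0.105	0.096
UK_CG	174	214	0.813	0.036	0.049	0.045
UK_GG	51	61	0.836	0.172	0.105	0.096
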