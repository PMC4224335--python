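# Published age/sex-adjusted logistic contrasts against the HV_CC reference
# (CI bounds normalised to lower-upper order)
term	coefficient	se	odds_ratio	ci_low	ci_high	p	q_smoother	q_bootstrap
const	3.63	0.449	NA	NA	NA	0.000	NA	NA
HV_CG	0.46	0.21	1.58	1.05	2.38	0.029	0.020	0.019
HV_GG	0.14	0.389	1.15	0.54	2.47	0.718	0.197	0.186
UK_CC	0.23	0.192	1.25	0.86	1.83	0.243	0.088	0.083
UK_CG	0.70	0.224	2.01	1.3	3.12	0.002	0.006	0.006
UK_GG	0.89	0.377	2.44	1.17	5.11	0.018	0.018	0.017
IW_CC	0.68	0.32	1.98	1.06	3.7	0.033	0.020	0.019
IW_CG	-0.15	0.277	0.86	0.5	1.48	0.585	0.177	0.167
IW_GG	1.54	1.07	4.65	0.57	37.86	0.151	0.065	0.062
JT_CC	0.64	0.27	1.90	1.12	3.22	0.018	0.018	0.017
JT_CG	0.36	0.321	1.44	0.77	2.69	0.261	0.088	0.083
JT_GG	1.10	0.651	3.01	0.84	10.77	0.091	0.046	0.043
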