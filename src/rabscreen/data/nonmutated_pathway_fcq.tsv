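gene	fc_TaG3_nonmut	q_TaG3_nonmut	fc_T1_nonmut	q_T1_nonmut	fc_T24_nonmut	q_T24_nonmut
CASP1	0.242	18.02	0.256	2.06	0.435	9.06
CD2AP	0.751	56.59	0.849	44.28	0.632	3.68
EEA1	0.495	12.50	0.688	11.55	0.604	2.68
GCC2	0.621	3.12	0.751	30.32	0.610	3.04
ICA1	0.695	46.67	0.618	3.35	0.435	1.31
MLPH	0.164	7.16	0.271	1.15	0.222	2.16
MYO5B	0.847	79.95	0.611	23.10	0.395	4.34
MYO5C	0.263	46.67	0.502	5.51	0.340	3.04
PIGR	0.195	23.76	0.305	4.46	0.246	1.76
RAB11A	0.859	76.84	0.678	17.40	0.498	1.41
RAB14	0.746	77.98	0.631	1.50	0.591	1.31
RAB38	0.157	6.89	0.277	1.15	0.405	21.73
RAB4A	0.693	19.62	0.764	27.99	0.541	3.68
RPH3AL	0.566	26.01	0.575	4.46	0.486	1.41
SYTL1	0.746	67.80	0.498	19.07	0.339	2.68
SYTL2	0.296	3.01	0.239	0.48	0.190	0.91
TBC1D30	0.410	10.31	0.506	3.35	0.413	3.68
TBC1D4	0.617	15.50	0.437	3.35	0.559	10.76
TRAPPC1	0.545	12.50	0.527	4.46	0.634	12.73
CAV1	4.566	40.49	4.912	0	10.843	0
ITGA5	1.808	26.01	1.874	0.60	2.848	0
KIF20A	4.050	53.97	4.024	4.46	3.700	5.43
LEPRE1	1.230	62.12	1.629	0.77	2.183	0
MICAL1	1.244	59.20	1.237	50.76	1.783	4.34
MICAL2	1.224	64.43	1.478	7.55	2.139	2.16
RAB23	0.892	79.95	1.483	33.03	2.674	2.68
RAB31	1.027	76.84	1.124	62.36	2.801	2.68
RABAC1	1.096	76.84	1.197	53.64	1.861	4.34
STXBP1	0.866	79.95	1.608	35.78	3.444	2.16
TMEM22	1.810	31.25	1.646	21.05	2.399	3.04
ZWINT	3.206	49.74	3.494	3.35	3.379	3.68
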