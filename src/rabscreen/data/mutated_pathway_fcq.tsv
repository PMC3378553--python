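gene	fc_TaG1G2_mut	q_TaG1G2_mut	fc_T1_mut	q_T1_mut	fc_T24_mut	q_T24_mut
ANKRD27	0.648	1.64	0.769	32.48	0.790	38.11
EEA1	0.574	0	0.691	4.55	0.748	23.80
GNAL	0.699	0.30	0.661	2.35	0.745	23.80
ICA1	0.833	26.37	0.666	2.88	0.570	10.45
MLPH	0.332	0.77	0.302	2.35	0.230	0.76
MYO5B	0.611	4.35	0.552	8.65	0.492	12.88
MYO5C	0.312	0.36	0.289	1.13	0.374	12.88
PIGR	0.216	0	0.265	4.55	0.274	5.46
RAB11FIP1	0.539	0.60	0.561	10.72	0.505	8.38
RAB11FIP2	0.572	3.25	0.578	8.65	0.521	1.63
RAB14	0.587	0.30	0.536	2.35	0.593	1.69
RAB20	0.513	0.60	0.484	4.55	0.435	5.46
RAB27A	0.542	0.30	0.664	40.85	1.126	70.25
RAB27B	0.486	0	0.653	17.18	0.469	1.16
RAB8B	0.583	0.77	0.766	62.91	0.647	23.80
RAB9A	0.617	0.36	0.582	2.88	0.591	4.45
RABGAP1L	0.619	4.35	0.641	40.85	1.156	70.25
RPH3AL	0.696	1.64	0.540	7.07	0.496	1.63
SYTL2	0.303	0.19	0.273	0.31	0.264	1.69
TBC1D30	0.459	0.19	0.492	1.34	0.427	1.63
UNC13B	0.572	0.77	0.615	7.07	0.502	1.63
CAV1	2.603	2.51	3.681	5.82	4.715	3.39
ITGA5	1.570	0.36	1.826	2.88	2.068	10.45
MICAL1	1.726	1.64	1.478	12.27	1.487	43.39
SDC1	1.621	3.25	1.387	22.11	1.525	43.39
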