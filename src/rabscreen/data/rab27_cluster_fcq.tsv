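gene	role	fc_TaG3_nonmut	q_TaG3_nonmut	fc_T1_nonmut	q_T1_nonmut	fc_T24_nonmut	q_T24_nonmut	fc_TaG1G2_mut	q_TaG1G2_mut	fc_T1_mut	q_T1_mut	fc_T24_mut	q_T24_mut
RAB27A	rab	0.510	34.08	0.757	50.76	1.176	60.73	0.542	0.30	0.664	40.85	1.126	70.25
RAB27B	rab	0.602	23.76	0.747	35.78	0.506	5.43	0.486	0	0.653	17.18	0.469	1.16
MADD	gef	0.849	12.85	0.777	7.55	0.787	6.72	0.980	49.78	0.879	45.50	0.801	20.04
TBC1D10A	gap	0.710	31.25	0.827	30.32	0.735	9.06	0.839	33.92	0.807	32.48	0.732	10.45
EXPH5	effector	1.597	62.12	1.039	68.42	0.826	58.06	0.587	10.22	0.702	22.11	0.594	8.38
GCC2	effector	0.621	3.12	0.751	30.32	0.610	3.04	0.890	44.88	0.776	24.58	0.780	43.39
MLPH	effector	0.164	7.16	0.271	1.15	0.222	2.16	0.332	0.77	0.302	2.35	0.230	0.76
MYRIP	effector	1.131	67.80	1.154	25.69	1.323	42.78	1.146	14.11	1.236	40.85	1.148	15.62
RPH3AL	effector	0.566	26.01	0.575	4.46	0.486	1.41	0.696	1.64	0.540	7.07	0.496	1.63
SYTL1	effector	0.746	67.80	0.498	19.07	0.339	2.68	1.182	26.37	0.891	68.81	0.812	75.24
SYTL2	effector	0.296	3.01	0.239	0.48	0.190	0.91	0.303	0.19	0.273	0.31	0.264	1.69
SYTL3	effector	0.806	12.50	0.728	3.83	0.821	24.09	0.724	0.60	0.776	3.73	0.768	12.88
SYTL4	effector	2.389	56.59	0.985	72.47	0.669	39.61	0.678	26.37	0.761	68.07	0.861	80.81
SYTL5	effector	0.822	79.64	1.074	64.73	0.710	14.94	0.845	43.92	1.054	62.34	0.813	64.39
UNC13D	effector	1.005	76.84	1.136	47.28	1.069	69.16	1.275	10.22	1.093	59.96	1.017	76.63
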