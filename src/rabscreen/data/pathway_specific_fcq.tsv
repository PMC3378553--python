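gene	fc_vs_normal	q_vs_normal	fc_cross	q_cross
SYTL1	0.339	2.68	0.418	1.72
LEPRE1	2.183	0	1.528	1.24
MICAL2	2.139	2.16	1.804	1.24
RAB23	2.674	2.68	1.920	4.08
STXBP1	3.444	2.16	2.314	2.53
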