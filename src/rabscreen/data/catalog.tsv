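symbol	role	clusters
RAB1A	rab	RAB1
RAB1B	rab	RAB1
RAB2A	rab	RAB2
RAB2B	rab	RAB2
RAB3A	rab	RAB3
RAB3B	rab	RAB3
RAB3C	rab	RAB3
RAB3D	rab	RAB3
RAB4A	rab	RAB4
RAB4B	rab	RAB4
RAB5A	rab	RAB5
RAB5B	rab	RAB5
RAB5C	rab	RAB5
RAB6A	rab	RAB6
RAB6B	rab	RAB6
RAB6C	rab	RAB6
RAB7A	rab	RAB7
RAB7B	rab	RAB7
RAB8A	rab	RAB8
RAB8B	rab	RAB8
RAB9A	rab	RAB9
RAB9B	rab	RAB9
RAB10	rab	RAB10
RAB11A	rab	RAB11
RAB11B	rab	RAB11
RAB12	rab	RAB12
RAB13	rab	RAB13
RAB14	rab	RAB14
RAB15	rab	RAB15
RAB17	rab	RAB17
RAB18	rab	RAB18
RAB19	rab	RAB19
RAB20	rab	RAB20
RAB21	rab	RAB21
RAB22A	rab	RAB22
RAB23	rab	RAB23
RAB24	rab	RAB24
RAB25	rab	RAB25
RAB26	rab	RAB26
RAB27A	rab	RAB27
RAB27B	rab	RAB27
RAB28	rab	RAB28
RAB30	rab	RAB30
RAB31	rab	RAB31
RAB32	rab	RAB32
RAB33A	rab	RAB33
RAB33B	rab	RAB33
RAB34	rab	RAB34
RAB35	rab	RAB35
RAB36	rab	RAB36
RAB37	rab	RAB37
RAB38	rab	RAB38
RAB39A	rab	RAB39
RAB39B	rab	RAB39
RAB40A	rab	RAB40
RAB40B	rab	RAB40
RAB40C	rab	RAB40
RAB41	rab	RAB41
RAB42	rab	RAB42
RAB43	rab	RAB43
RAB44	rab	RAB44
MADD	gef	RAB27
TBC1D10A	gap	RAB27
EXPH5	effector	RAB27
GCC2	effector	RAB27;RAB6
MLPH	effector	RAB27
MYRIP	effector	RAB27
RPH3A	effector	RAB27
RPH3AL	effector	RAB27
SYTL1	effector	RAB27
SYTL2	effector	RAB27
SYTL3	effector	RAB27
SYTL4	effector	RAB27
SYTL5	effector	RAB27
UNC13D	effector	RAB27
TRAPPC1	gef	RAB1
RIN1	gef	RAB5
CCZ1	gef	RAB7
ANKRD27	gef	RAB21
TBC1D30	gap	RAB8
TBC1D4	gap	RAB10;RAB14
TBC1D3B	gap	RAB5
RABGAP1L	gap	RAB22
MICAL1	effector	RAB1
MICAL2	effector	RAB1
LEPRE1	effector	RAB1
RABAC1	effector	RAB1
ICA1	effector	RAB2
TMEM22	effector	RAB2
STXBP1	effector	RAB3
UNC13B	effector	RAB3
GNAL	effector	RAB3
YWHAQ	effector	RAB3
CD2AP	effector	RAB4
SDC1	effector	RAB4
EEA1	effector	RAB5
CAV1	effector	RAB5
F8A1	effector	RAB5
KIF20A	effector	RAB6
ZWINT	effector	RAB6
MYO5C	effector	RAB8
MYO5B	effector	RAB11
RAB11FIP1	effector	RAB11
RAB11FIP2	effector	RAB11
REP15	effector	RAB15
PIGR	effector	RAB25
ITGA5	effector	RAB25
CASP1	effector	RAB39
GMCL1	effector	RAB39
SYNGEF001	gef	RAB1;RAB10
SYNGEF002	gef	RAB1;RAB21
SYNGEF003	gef	RAB1;RAB22
SYNGEF004	gef	RAB1;RAB31
SYNGEF005	gef	RAB1;RAB35
SYNGEF006	gef	RAB1;RAB35
SYNGEF007	gef	RAB1;RAB35
SYNGEF008	gef	RAB3
SYNGEF009	gef	RAB3
SYNGEF010	gef	RAB3
SYNGEF011	gef	RAB5
SYNGEF012	gef	RAB5
SYNGEF013	gef	RAB5
SYNGEF014	gef	RAB5
SYNGEF015	gef	RAB5
SYNGEF016	gef	RAB5
SYNGEF017	gef	RAB8
SYNGEF018	gef	RAB8
SYNGAP001	gap	RAB1;RAB7;RAB41
SYNGAP002	gap	RAB2;RAB8;RAB43
SYNGAP003	gap	RAB2;RAB10
SYNGAP004	gap	RAB2;RAB10
SYNGAP005	gap	RAB3;RAB11
SYNGAP006	gap	RAB3;RAB11
SYNGAP007	gap	RAB3;RAB11
SYNGAP008	gap	RAB4;RAB17
SYNGAP009	gap	RAB4;RAB21
SYNGAP010	gap	RAB5;RAB22
SYNGAP011	gap	RAB5;RAB23
SYNGAP012	gap	RAB5;RAB34
SYNGAP013	gap	RAB5;RAB35
SYNGAP014	gap	RAB6;RAB36
SYNGAP015	gap	RAB6;RAB39
SYNEF001	effector	RAB1;RAB9
SYNEF002	effector	RAB1;RAB9
SYNEF003	effector	RAB1;RAB9
SYNEF004	effector	RAB1;RAB9
SYNEF005	effector	RAB1;RAB9
SYNEF006	effector	RAB1;RAB9
SYNEF007	effector	RAB1;RAB9
SYNEF008	effector	RAB1;RAB9
SYNEF009	effector	RAB1;RAB10
SYNEF010	effector	RAB1;RAB10
SYNEF011	effector	RAB1;RAB10
SYNEF012	effector	RAB1;RAB10
SYNEF013	effector	RAB1;RAB10
SYNEF014	effector	RAB1;RAB10
SYNEF015	effector	RAB2;RAB10
SYNEF016	effector	RAB2;RAB10
SYNEF017	effector	RAB2;RAB10
SYNEF018	effector	RAB2;RAB11
SYNEF019	effector	RAB3;RAB11
SYNEF020	effector	RAB3;RAB11
SYNEF021	effector	RAB3;RAB11
SYNEF022	effector	RAB3;RAB11
SYNEF023	effector	RAB3;RAB11
SYNEF024	effector	RAB3;RAB11
SYNEF025	effector	RAB3;RAB11
SYNEF026	effector	RAB3;RAB11
SYNEF027	effector	RAB3;RAB11
SYNEF028	effector	RAB3;RAB11
SYNEF029	effector	RAB3;RAB11
SYNEF030	effector	RAB3;RAB11
SYNEF031	effector	RAB3;RAB11
SYNEF032	effector	RAB3;RAB11
SYNEF033	effector	RAB3;RAB11
SYNEF034	effector	RAB3;RAB11
SYNEF035	effector	RAB3;RAB11
SYNEF036	effector	RAB3;RAB11
SYNEF037	effector	RAB3;RAB11
SYNEF038	effector	RAB4;RAB11
SYNEF039	effector	RAB4;RAB11
SYNEF040	effector	RAB4;RAB11
SYNEF041	effector	RAB4;RAB11
SYNEF042	effector	RAB4;RAB11
SYNEF043	effector	RAB4;RAB11
SYNEF044	effector	RAB4;RAB12
SYNEF045	effector	RAB4;RAB13
SYNEF046	effector	RAB4;RAB13
SYNEF047	effector	RAB4;RAB13
SYNEF048	effector	RAB4;RAB13
SYNEF049	effector	RAB4;RAB13
SYNEF050	effector	RAB4;RAB13
SYNEF051	effector	RAB4;RAB13
SYNEF052	effector	RAB4;RAB13
SYNEF053	effector	RAB4;RAB13
SYNEF054	effector	RAB4;RAB13
SYNEF055	effector	RAB5;RAB14
SYNEF056	effector	RAB5;RAB14
SYNEF057	effector	RAB5;RAB14
SYNEF058	effector	RAB5;RAB14
SYNEF059	effector	RAB5;RAB14
SYNEF060	effector	RAB5;RAB15
SYNEF061	effector	RAB5;RAB15
SYNEF062	effector	RAB5;RAB15
SYNEF063	effector	RAB5;RAB15
SYNEF064	effector	RAB5;RAB15
SYNEF065	effector	RAB5;RAB17
SYNEF066	effector	RAB5;RAB19
SYNEF067	effector	RAB5;RAB19
SYNEF068	effector	RAB5;RAB19
SYNEF069	effector	RAB5;RAB20
SYNEF070	effector	RAB5;RAB22
SYNEF071	effector	RAB5;RAB22
SYNEF072	effector	RAB5;RAB22
SYNEF073	effector	RAB5;RAB22
SYNEF074	effector	RAB5;RAB22
SYNEF075	effector	RAB5;RAB24
SYNEF076	effector	RAB5;RAB24
SYNEF077	effector	RAB5;RAB25
SYNEF078	effector	RAB5;RAB25
SYNEF079	effector	RAB5;RAB25
SYNEF080	effector	RAB6;RAB25
SYNEF081	effector	RAB6;RAB25
SYNEF082	effector	RAB6;RAB26
SYNEF083	effector	RAB6;RAB30
SYNEF084	effector	RAB6;RAB30
SYNEF085	effector	RAB6;RAB30
SYNEF086	effector	RAB6;RAB31
SYNEF087	effector	RAB6;RAB31
SYNEF088	effector	RAB6;RAB31
SYNEF089	effector	RAB6;RAB32
SYNEF090	effector	RAB6;RAB32
SYNEF091	effector	RAB6;RAB33
SYNEF092	effector	RAB6;RAB33
SYNEF093	effector	RAB6;RAB33
SYNEF094	effector	RAB6;RAB33
SYNEF095	effector	RAB6;RAB33
SYNEF096	effector	RAB6;RAB33
SYNEF097	effector	RAB6;RAB33
SYNEF098	effector	RAB6;RAB33
SYNEF099	effector	RAB6;RAB34
SYNEF100	effector	RAB6;RAB34
SYNEF101	effector	RAB7;RAB35
SYNEF102	effector	RAB7;RAB35
SYNEF103	effector	RAB7;RAB35
SYNEF104	effector	RAB7;RAB35
SYNEF105	effector	RAB7;RAB35
SYNEF106	effector	RAB7;RAB36
SYNEF107	effector	RAB7;RAB36
SYNEF108	effector	RAB7;RAB36
SYNEF109	effector	RAB7;RAB36
SYNEF110	effector	RAB7;RAB36
SYNEF111	effector	RAB7;RAB36
SYNEF112	effector	RAB7;RAB37
SYNEF113	effector	RAB7;RAB37
SYNEF114	effector	RAB7;RAB38
SYNEF115	effector	RAB8;RAB39
SYNEF116	effector	RAB8;RAB40
SYNEF117	effector	RAB8;RAB40
SYNEF118	effector	RAB8;RAB41
SYNEF119	effector	RAB8;RAB41
SYNEF120	effector	RAB8;RAB41
SYNEF121	effector	RAB8
SYNEF122	effector	RAB8
SYNEF123	effector	RAB8
SYNEF124	effector	RAB8
SYNEF125	effector	RAB8
SYNEF126	effector	RAB8
SYNEF127	effector	RAB8
SYNEF128	effector	RAB8
SYNEF129	effector	RAB8
SYNEF130	effector	RAB8
SYNEF131	effector	RAB8
SYNEF132	effector	RAB8
SYNEF133	effector	RAB8
SYNEF134	effector	RAB8
SYNEF135	effector	RAB8
SYNEF136	effector	RAB9
GDI1	general_machinery	
GDI2	general_machinery	
CHM	general_machinery	
CHML	general_machinery	
RABGGTA	general_machinery	
RABGGTB	general_machinery	
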