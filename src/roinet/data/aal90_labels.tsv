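index	name	abbreviation
0	Precentral_L	PreCG.L
1	Precentral_R	PreCG.R
2	Frontal_Sup_L	SFGdor.L
3	Frontal_Sup_R	SFGdor.R
4	Frontal_Sup_Orb_L	ORBsup.L
5	Frontal_Sup_Orb_R	ORBsup.R
6	Frontal_Mid_L	MFG.L
7	Frontal_Mid_R	MFG.R
8	Frontal_Mid_Orb_L	ORBmid.L
9	Frontal_Mid_Orb_R	ORBmid.R
10	Frontal_Inf_Oper_L	IFGoperc.L
11	Frontal_Inf_Oper_R	IFGoperc.R
12	Frontal_Inf_Tri_L	IFGtriang.L
13	Frontal_Inf_Tri_R	IFGtriang.R
14	Frontal_Inf_Orb_L	ORBinf.L
15	Frontal_Inf_Orb_R	ORBinf.R
16	Rolandic_Oper_L	ROL.L
17	Rolandic_Oper_R	ROL.R
18	Supp_Motor_Area_L	SMA.L
19	Supp_Motor_Area_R	SMA.R
20	Olfactory_L	OLF.L
21	Olfactory_R	OLF.R
22	Frontal_Sup_Medial_L	SFGmed.L
23	Frontal_Sup_Medial_R	SFGmed.R
24	Frontal_Med_Orb_L	ORBsupmed.L
25	Frontal_Med_Orb_R	ORBsupmed.R
26	Rectus_L	REC.L
27	Rectus_R	REC.R
28	Insula_L	INS.L
29	Insula_R	INS.R
30	Cingulum_Ant_L	ACG.L
31	Cingulum_Ant_R	ACG.R
32	Cingulum_Mid_L	DCG.L
33	Cingulum_Mid_R	DCG.R
34	Cingulum_Post_L	PCG.L
35	Cingulum_Post_R	PCG.R
36	Hippocampus_L	HIP.L
37	Hippocampus_R	HIP.R
38	ParaHippocampal_L	PHG.L
39	ParaHippocampal_R	PHG.R
40	Amygdala_L	AMYG.L
41	Amygdala_R	AMYG.R
42	Calcarine_L	CAL.L
43	Calcarine_R	CAL.R
44	Cuneus_L	CUN.L
45	Cuneus_R	CUN.R
46	Lingual_L	LING.L
47	Lingual_R	LING.R
48	Occipital_Sup_L	SOG.L
49	Occipital_Sup_R	SOG.R
50	Occipital_Mid_L	MOG.L
51	Occipital_Mid_R	MOG.R
52	Occipital_Inf_L	IOG.L
53	Occipital_Inf_R	IOG.R
54	Fusiform_L	FFG.L
55	Fusiform_R	FFG.R
56	Postcentral_L	PoCG.L
57	Postcentral_R	PoCG.R
58	Parietal_Sup_L	SPG.L
59	Parietal_Sup_R	SPG.R
60	Parietal_Inf_L	IPL.L
61	Parietal_Inf_R	IPL.R
62	SupraMarginal_L	SMG.L
63	SupraMarginal_R	SMG.R
64	Angular_L	ANG.L
65	Angular_R	ANG.R
66	Precuneus_L	PCUN.L
67	Precuneus_R	PCUN.R
68	Paracentral_Lobule_L	PCL.L
69	Paracentral_Lobule_R	PCL.R
70	Caudate_L	CAU.L
71	Caudate_R	CAU.R
72	Putamen_L	PUT.L
73	Putamen_R	PUT.R
74	Pallidum_L	PAL.L
75	Pallidum_R	PAL.R
76	Thalamus_L	THA.L
77	Thalamus_R	THA.R
78	Heschl_L	HES.L
79	Heschl_R	HES.R
80	Temporal_Sup_L	STG.L
81	Temporal_Sup_R	STG.R
82	Temporal_Pole_Sup_L	TPOsup.L
83	Temporal_Pole_Sup_R	TPOsup.R
84	Temporal_Mid_L	MTG.L
85	Temporal_Mid_R	MTG.R
86	Temporal_Pole_Mid_L	TPOmid.L
87	Temporal_Pole_Mid_R	TPOmid.R
88	Temporal_Inf_L	ITG.L
89	Temporal_Inf_R	ITG.R
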