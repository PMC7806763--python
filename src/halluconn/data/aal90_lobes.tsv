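node_id	label	lobe	hemisphere
0	Precentral_L	central	L
1	Precentral_R	central	R
2	Frontal_Sup_L	frontal	L
3	Frontal_Sup_R	frontal	R
4	Frontal_Sup_Orb_L	frontal	L
5	Frontal_Sup_Orb_R	frontal	R
6	Frontal_Mid_L	frontal	L
7	Frontal_Mid_R	frontal	R
8	Frontal_Mid_Orb_L	frontal	L
9	Frontal_Mid_Orb_R	frontal	R
10	Frontal_Inf_Oper_L	frontal	L
11	Frontal_Inf_Oper_R	frontal	R
12	Frontal_Inf_Tri_L	frontal	L
13	Frontal_Inf_Tri_R	frontal	R
14	Frontal_Inf_Orb_L	frontal	L
15	Frontal_Inf_Orb_R	frontal	R
16	Rolandic_Oper_L	central	L
17	Rolandic_Oper_R	central	R
18	Supp_Motor_Area_L	frontal	L
19	Supp_Motor_Area_R	frontal	R
20	Olfactory_L	frontal	L
21	Olfactory_R	frontal	R
22	Frontal_Sup_Medial_L	frontal	L
23	Frontal_Sup_Medial_R	frontal	R
24	Frontal_Med_Orb_L	frontal	L
25	Frontal_Med_Orb_R	frontal	R
26	Rectus_L	frontal	L
27	Rectus_R	frontal	R
28	Insula_L	insula_cingulate	L
29	Insula_R	insula_cingulate	R
30	Cingulum_Ant_L	insula_cingulate	L
31	Cingulum_Ant_R	insula_cingulate	R
32	Cingulum_Mid_L	insula_cingulate	L
33	Cingulum_Mid_R	insula_cingulate	R
34	Cingulum_Post_L	insula_cingulate	L
35	Cingulum_Post_R	insula_cingulate	R
36	Hippocampus_L	temporal	L
37	Hippocampus_R	temporal	R
38	ParaHippocampal_L	temporal	L
39	ParaHippocampal_R	temporal	R
40	Amygdala_L	temporal	L
41	Amygdala_R	temporal	R
42	Calcarine_L	occipital	L
43	Calcarine_R	occipital	R
44	Cuneus_L	occipital	L
45	Cuneus_R	occipital	R
46	Lingual_L	occipital	L
47	Lingual_R	occipital	R
48	Occipital_Sup_L	occipital	L
49	Occipital_Sup_R	occipital	R
50	Occipital_Mid_L	occipital	L
51	Occipital_Mid_R	occipital	R
52	Occipital_Inf_L	occipital	L
53	Occipital_Inf_R	occipital	R
54	Fusiform_L	temporal	L
55	Fusiform_R	temporal	R
56	Postcentral_L	central	L
57	Postcentral_R	central	R
58	Parietal_Sup_L	parietal	L
59	Parietal_Sup_R	parietal	R
60	Parietal_Inf_L	parietal	L
61	Parietal_Inf_R	parietal	R
62	SupraMarginal_L	parietal	L
63	SupraMarginal_R	parietal	R
64	Angular_L	parietal	L
65	Angular_R	parietal	R
66	Precuneus_L	parietal	L
67	Precuneus_R	parietal	R
68	Paracentral_Lobule_L	central	L
69	Paracentral_Lobule_R	central	R
70	Caudate_L	central	L
71	Caudate_R	central	R
72	Putamen_L	central	L
73	Putamen_R	central	R
74	Pallidum_L	central	L
75	Pallidum_R	central	R
76	Thalamus_L	central	L
77	Thalamus_R	central	R
78	Heschl_L	temporal	L
79	Heschl_R	temporal	R
80	Temporal_Sup_L	temporal	L
81	Temporal_Sup_R	temporal	R
82	Temporal_Pole_Sup_L	temporal	L
83	Temporal_Pole_Sup_R	temporal	R
84	Temporal_Mid_L	temporal	L
85	Temporal_Mid_R	temporal	R
86	Temporal_Pole_Mid_L	temporal	L
87	Temporal_Pole_Mid_R	temporal	R
88	Temporal_Inf_L	temporal	L
89	Temporal_Inf_R	temporal	R
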