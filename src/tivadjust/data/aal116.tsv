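index	name	hemisphere
1	Precentral_L	left
2	Precentral_R	right
3	Frontal_Sup_L	left
4	Frontal_Sup_R	right
5	Frontal_Sup_Orb_L	left
6	Frontal_Sup_Orb_R	right
7	Frontal_Mid_L	left
8	Frontal_Mid_R	right
9	Frontal_Mid_Orb_L	left
10	Frontal_Mid_Orb_R	right
11	Frontal_Inf_Oper_L	left
12	Frontal_Inf_Oper_R	right
13	Frontal_Inf_Tri_L	left
14	Frontal_Inf_Tri_R	right
15	Frontal_Inf_Orb_L	left
16	Frontal_Inf_Orb_R	right
17	Rolandic_Oper_L	left
18	Rolandic_Oper_R	right
19	Supp_Motor_Area_L	left
20	Supp_Motor_Area_R	right
21	Olfactory_L	left
22	Olfactory_R	right
23	Frontal_Sup_Medial_L	left
24	Frontal_Sup_Medial_R	right
25	Frontal_Med_Orb_L	left
26	Frontal_Med_Orb_R	right
27	Rectus_L	left
28	Rectus_R	right
29	Insula_L	left
30	Insula_R	right
31	Cingulum_Ant_L	left
32	Cingulum_Ant_R	right
33	Cingulum_Mid_L	left
34	Cingulum_Mid_R	right
35	Cingulum_Post_L	left
36	Cingulum_Post_R	right
37	Hippocampus_L	left
38	Hippocampus_R	right
39	ParaHippocampal_L	left
40	ParaHippocampal_R	right
41	Amygdala_L	left
42	Amygdala_R	right
43	Calcarine_L	left
44	Calcarine_R	right
45	Cuneus_L	left
46	Cuneus_R	right
47	Lingual_L	left
48	Lingual_R	right
49	Occipital_Sup_L	left
50	Occipital_Sup_R	right
51	Occipital_Mid_L	left
52	Occipital_Mid_R	right
53	Occipital_Inf_L	left
54	Occipital_Inf_R	right
55	Fusiform_L	left
56	Fusiform_R	right
57	Postcentral_L	left
58	Postcentral_R	right
59	Parietal_Sup_L	left
60	Parietal_Sup_R	right
61	Parietal_Inf_L	left
62	Parietal_Inf_R	right
63	SupraMarginal_L	left
64	SupraMarginal_R	right
65	Angular_L	left
66	Angular_R	right
67	Precuneus_L	left
68	Precuneus_R	right
69	Paracentral_Lobule_L	left
70	Paracentral_Lobule_R	right
71	Caudate_L	left
72	Caudate_R	right
73	Putamen_L	left
74	Putamen_R	right
75	Pallidum_L	left
76	Pallidum_R	right
77	Thalamus_L	left
78	Thalamus_R	right
79	Heschl_L	left
80	Heschl_R	right
81	Temporal_Sup_L	left
82	Temporal_Sup_R	right
83	Temporal_Pole_Sup_L	left
84	Temporal_Pole_Sup_R	right
85	Temporal_Mid_L	left
86	Temporal_Mid_R	right
87	Temporal_Pole_Mid_L	left
88	Temporal_Pole_Mid_R	right
89	Temporal_Inf_L	left
90	Temporal_Inf_R	right
91	Cerebelum_Crus1_L	left
92	Cerebelum_Crus1_R	right
93	Cerebelum_Crus2_L	left
94	Cerebelum_Crus2_R	right
95	Cerebelum_3_L	left
96	Cerebelum_3_R	right
97	Cerebelum_4_5_L	left
98	Cerebelum_4_5_R	right
99	Cerebelum_6_L	left
100	Cerebelum_6_R	right
101	Cerebelum_7b_L	left
102	Cerebelum_7b_R	right
103	Cerebelum_8_L	left
104	Cerebelum_8_R	right
105	Cerebelum_9_L	left
106	Cerebelum_9_R	right
107	Cerebelum_10_L	left
108	Cerebelum_10_R	right
109	Vermis_1_2	vermis
110	Vermis_3	vermis
111	Vermis_4_5	vermis
112	Vermis_6	vermis
113	Vermis_7	vermis
114	Vermis_8	vermis
115	Vermis_9	vermis
116	Vermis_10	vermis
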