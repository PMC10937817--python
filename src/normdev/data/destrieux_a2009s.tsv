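region_id	name	hemisphere	kind	lobe_group
0	lh_G_and_S_frontomargin	left	gyral	extratemporal
1	lh_G_and_S_occipital_inf	left	gyral	extratemporal
2	lh_G_and_S_paracentral	left	gyral	extratemporal
3	lh_G_and_S_subcentral	left	gyral	extratemporal
4	lh_G_and_S_transv_frontopol	left	gyral	extratemporal
5	lh_G_and_S_cingul-Ant	left	gyral	extratemporal
6	lh_G_and_S_cingul-Mid-Ant	left	gyral	extratemporal
7	lh_G_and_S_cingul-Mid-Post	left	gyral	extratemporal
8	lh_G_cingul-Post-dorsal	left	gyral	extratemporal
9	lh_G_cingul-Post-ventral	left	gyral	extratemporal
10	lh_G_cuneus	left	gyral	extratemporal
11	lh_G_front_inf-Opercular	left	gyral	extratemporal
12	lh_G_front_inf-Orbital	left	gyral	extratemporal
13	lh_G_front_inf-Triangul	left	gyral	extratemporal
14	lh_G_front_middle	left	gyral	extratemporal
15	lh_G_front_sup	left	gyral	extratemporal
16	lh_G_Ins_lg_and_S_cent_ins	left	gyral	extratemporal
17	lh_G_insular_short	left	gyral	extratemporal
18	lh_G_occipital_middle	left	gyral	extratemporal
19	lh_G_occipital_sup	left	gyral	extratemporal
20	lh_G_oc-temp_lat-fusifor	left	gyral	temporal
21	lh_G_oc-temp_med-Lingual	left	gyral	temporal
22	lh_G_oc-temp_med-Parahip	left	gyral	temporal
23	lh_G_orbital	left	gyral	extratemporal
24	lh_G_pariet_inf-Angular	left	gyral	extratemporal
25	lh_G_pariet_inf-Supramar	left	gyral	extratemporal
26	lh_G_parietal_sup	left	gyral	extratemporal
27	lh_G_postcentral	left	gyral	extratemporal
28	lh_G_precentral	left	gyral	extratemporal
29	lh_G_precuneus	left	gyral	extratemporal
30	lh_G_rectus	left	gyral	extratemporal
31	lh_G_subcallosal	left	gyral	extratemporal
32	lh_G_temp_sup-G_T_transv	left	gyral	temporal
33	lh_G_temp_sup-Lateral	left	gyral	temporal
34	lh_G_temp_sup-Plan_polar	left	gyral	temporal
35	lh_G_temp_sup-Plan_tempo	left	gyral	temporal
36	lh_G_temporal_inf	left	gyral	temporal
37	lh_G_temporal_middle	left	gyral	temporal
38	lh_Lat_Fis-ant-Horizont	left	sulcal	extratemporal
39	lh_Lat_Fis-ant-Vertical	left	sulcal	extratemporal
40	lh_Lat_Fis-post	left	sulcal	extratemporal
41	lh_Pole_occipital	left	gyral	extratemporal
42	lh_Pole_temporal	left	gyral	temporal
43	lh_S_calcarine	left	sulcal	extratemporal
44	lh_S_central	left	sulcal	extratemporal
45	lh_S_cingul-Marginalis	left	sulcal	extratemporal
46	lh_S_circular_insula_ant	left	sulcal	extratemporal
47	lh_S_circular_insula_inf	left	sulcal	extratemporal
48	lh_S_circular_insula_sup	left	sulcal	extratemporal
49	lh_S_collat_transv_ant	left	sulcal	extratemporal
50	lh_S_collat_transv_post	left	sulcal	extratemporal
51	lh_S_front_inf	left	sulcal	extratemporal
52	lh_S_front_middle	left	sulcal	extratemporal
53	lh_S_front_sup	left	sulcal	extratemporal
54	lh_S_interm_prim-Jensen	left	sulcal	extratemporal
55	lh_S_intrapariet_and_P_trans	left	sulcal	extratemporal
56	lh_S_oc_middle_and_Lunatus	left	sulcal	extratemporal
57	lh_S_oc_sup_and_transversal	left	sulcal	extratemporal
58	lh_S_occipital_ant	left	sulcal	extratemporal
59	lh_S_oc-temp_lat	left	sulcal	temporal
60	lh_S_oc-temp_med_and_Lingual	left	sulcal	temporal
61	lh_S_orbital_lateral	left	sulcal	extratemporal
62	lh_S_orbital_med-olfact	left	sulcal	extratemporal
63	lh_S_orbital-H_Shaped	left	sulcal	extratemporal
64	lh_S_parieto_occipital	left	sulcal	extratemporal
65	lh_S_pericallosal	left	sulcal	extratemporal
66	lh_S_postcentral	left	sulcal	extratemporal
67	lh_S_precentral-inf-part	left	sulcal	extratemporal
68	lh_S_precentral-sup-part	left	sulcal	extratemporal
69	lh_S_suborbital	left	sulcal	extratemporal
70	lh_S_subparietal	left	sulcal	extratemporal
71	lh_S_temporal_inf	left	sulcal	temporal
72	lh_S_temporal_sup	left	sulcal	temporal
73	lh_S_temporal_transverse	left	sulcal	temporal
74	rh_G_and_S_frontomargin	right	gyral	extratemporal
75	rh_G_and_S_occipital_inf	right	gyral	extratemporal
76	rh_G_and_S_paracentral	right	gyral	extratemporal
77	rh_G_and_S_subcentral	right	gyral	extratemporal
78	rh_G_and_S_transv_frontopol	right	gyral	extratemporal
79	rh_G_and_S_cingul-Ant	right	gyral	extratemporal
80	rh_G_and_S_cingul-Mid-Ant	right	gyral	extratemporal
81	rh_G_and_S_cingul-Mid-Post	right	gyral	extratemporal
82	rh_G_cingul-Post-dorsal	right	gyral	extratemporal
83	rh_G_cingul-Post-ventral	right	gyral	extratemporal
84	rh_G_cuneus	right	gyral	extratemporal
85	rh_G_front_inf-Opercular	right	gyral	extratemporal
86	rh_G_front_inf-Orbital	right	gyral	extratemporal
87	rh_G_front_inf-Triangul	right	gyral	extratemporal
88	rh_G_front_middle	right	gyral	extratemporal
89	rh_G_front_sup	right	gyral	extratemporal
90	rh_G_Ins_lg_and_S_cent_ins	right	gyral	extratemporal
91	rh_G_insular_short	right	gyral	extratemporal
92	rh_G_occipital_middle	right	gyral	extratemporal
93	rh_G_occipital_sup	right	gyral	extratemporal
94	rh_G_oc-temp_lat-fusifor	right	gyral	temporal
95	rh_G_oc-temp_med-Lingual	right	gyral	temporal
96	rh_G_oc-temp_med-Parahip	right	gyral	temporal
97	rh_G_orbital	right	gyral	extratemporal
98	rh_G_pariet_inf-Angular	right	gyral	extratemporal
99	rh_G_pariet_inf-Supramar	right	gyral	extratemporal
100	rh_G_parietal_sup	right	gyral	extratemporal
101	rh_G_postcentral	right	gyral	extratemporal
102	rh_G_precentral	right	gyral	extratemporal
103	rh_G_precuneus	right	gyral	extratemporal
104	rh_G_rectus	right	gyral	extratemporal
105	rh_G_subcallosal	right	gyral	extratemporal
106	rh_G_temp_sup-G_T_transv	right	gyral	temporal
107	rh_G_temp_sup-Lateral	right	gyral	temporal
108	rh_G_temp_sup-Plan_polar	right	gyral	temporal
109	rh_G_temp_sup-Plan_tempo	right	gyral	temporal
110	rh_G_temporal_inf	right	gyral	temporal
111	rh_G_temporal_middle	right	gyral	temporal
112	rh_Lat_Fis-ant-Horizont	right	sulcal	extratemporal
113	rh_Lat_Fis-ant-Vertical	right	sulcal	extratemporal
114	rh_Lat_Fis-post	right	sulcal	extratemporal
115	rh_Pole_occipital	right	gyral	extratemporal
116	rh_Pole_temporal	right	gyral	temporal
117	rh_S_calcarine	right	sulcal	extratemporal
118	rh_S_central	right	sulcal	extratemporal
119	rh_S_cingul-Marginalis	right	sulcal	extratemporal
120	rh_S_circular_insula_ant	right	sulcal	extratemporal
121	rh_S_circular_insula_inf	right	sulcal	extratemporal
122	rh_S_circular_insula_sup	right	sulcal	extratemporal
123	rh_S_collat_transv_ant	right	sulcal	extratemporal
124	rh_S_collat_transv_post	right	sulcal	extratemporal
125	rh_S_front_inf	right	sulcal	extratemporal
126	rh_S_front_middle	right	sulcal	extratemporal
127	rh_S_front_sup	right	sulcal	extratemporal
128	rh_S_interm_prim-Jensen	right	sulcal	extratemporal
129	rh_S_intrapariet_and_P_trans	right	sulcal	extratemporal
130	rh_S_oc_middle_and_Lunatus	right	sulcal	extratemporal
131	rh_S_oc_sup_and_transversal	right	sulcal	extratemporal
132	rh_S_occipital_ant	right	sulcal	extratemporal
133	rh_S_oc-temp_lat	right	sulcal	temporal
134	rh_S_oc-temp_med_and_Lingual	right	sulcal	temporal
135	rh_S_orbital_lateral	right	sulcal	extratemporal
136	rh_S_orbital_med-olfact	right	sulcal	extratemporal
137	rh_S_orbital-H_Shaped	right	sulcal	extratemporal
138	rh_S_parieto_occipital	right	sulcal	extratemporal
139	rh_S_pericallosal	right	sulcal	extratemporal
140	rh_S_postcentral	right	sulcal	extratemporal
141	rh_S_precentral-inf-part	right	sulcal	extratemporal
142	rh_S_precentral-sup-part	right	sulcal	extratemporal
143	rh_S_suborbital	right	sulcal	extratemporal
144	rh_S_subparietal	right	sulcal	extratemporal
145	rh_S_temporal_inf	right	sulcal	temporal
146	rh_S_temporal_sup	right	sulcal	temporal
147	rh_S_temporal_transverse	right	sulcal	temporal
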