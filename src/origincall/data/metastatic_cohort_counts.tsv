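section	class_label	grouped	total	tpr	fpr	tp	tn	fp	fn	precision	recall	f1	n_diagnosis	n_biopsy_site	n_organ_system	n_other
metastatic_site	Mesothelioma	0	1	1.00	0.00	1	130	0	0	1.00	1.00	1.00	1	0	0	0
metastatic_site	Colorectal AC	0	21	0.81	0.00	17	114	0	4	1.00	0.81	0.89	17	1	2	1
metastatic_site	UCEC	0	5	0.40	0.00	2	129	0	3	1.00	0.40	0.57	2	0	1	2
metastatic_site	Uterine carcinosarcoma	0	4	0.25	0.00	1	130	0	3	1.00	0.25	0.40	1	0	2	1
metastatic_site	Breast carcinoma	0	65	0.97	0.03	63	68	2	2	0.97	0.97	0.97	63	1	0	1
metastatic_site	LNG_group	1	14	1.00	0.01	14	117	1	0	0.93	1.00	0.97	14	0	0	0
metastatic_site	Sarcoma	0	17	0.53	0.01	9	122	1	8	0.90	0.53	0.67	9	1	0	7
metastatic_site	Ovarian carcinoma	0	7	0.86	0.01	6	160	1	1	0.86	0.86	0.86	6	0	0	1
metastatic_site	Pancreatic AC	0	9	0.33	0.01	3	158	1	6	0.75	0.33	0.46	3	1	4	1
metastatic_site	MISC_group	1	9	0.88	0.00	8	125	1	1	0.73	0.88	0.77	8	0	0	1
metastatic_site	Cholangiocarcinoma	0	5	0.80	0.02	4	127	2	1	0.67	0.80	0.73	4	0	1	0
metastatic_site	GEJ_group	1	11	0.29	0.01	3	151	5	8	0.31	0.29	0.26	3	3	1	4
primary_site	CNS_group	1	6	1.00	0.00	6	23	0	0	1.00	1.00	1.00	6	0	0	0
primary_site	Breast carcinoma	0	4	1.00	0.00	4	25	0	0	1.00	1.00	1.00	4	0	0	0
primary_site	Colorectal AC	0	1	1.00	0.00	1	28	0	0	1.00	1.00	1.00	1	0	0	0
primary_site	GEJ_group	1	1	1.00	0.00	1	28	0	0	1.00	1.00	1.00	1	0	0	0
primary_site	MISC_group	1	2	1.00	0.00	2	27	0	0	1.00	1.00	1.00	2	0	0	0
primary_site	Pancreatic AC	0	2	1.00	0.00	2	27	0	0	1.00	1.00	1.00	2	0	0	0
primary_site	Uterine carcinosarcoma	0	1	1.00	0.00	1	28	0	0	1.00	1.00	1.00	1	0	0	0
primary_site	Sarcoma	0	6	0.83	0.00	5	24	0	1	1.00	0.83	0.91	5	0	0	1
primary_site	Mesothelioma	0	4	0.75	0.00	3	26	0	1	1.00	0.75	0.86	3	0	0	1
primary_site	LNG_group	1	5	0.88	0.02	4	23	1	1	0.75	0.88	0.76	4	0	1	0
primary_site	UCEC	0	1	0.00	0.00	0	29	0	1	0.00	0.00	0.00	0	0	1	0
total	Total	0	201	0.76	0.005	160	3128	19	41	0.86	0.76	0.79	160	7	13	21
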