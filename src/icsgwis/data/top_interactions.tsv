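snp	chrom	major	minor	gene	or_disc	ci_low_disc	ci_high_disc	p_disc_printed	or_rep	ci_low_rep	ci_high_rep	p_rep_printed	p_joint_printed
rs34631960	15	CTT	C	THSD4	2.33	1.61	3.38	7.08e-06	1.82	1.23	2.7	2.97e-03	3.64e-08
rs2328386	6	C	T	HIVEP2	0.33	0.2	0.55	1.86e-05	0.51	0.34	0.77	1.49e-03	4.98e-08
rs290119	5	G	A	.	2.38	1.6	3.53	1.76e-05	1.96	1.28	3	1.99e-03	6.13e-08
rs290122	5	C	T	.	2.38	1.6	3.53	1.76e-05	1.96	1.28	3	1.99e-03	6.13e-08
rs58836160	5	T	TA	.	2.38	1.6	3.53	1.76e-05	1.96	1.28	3	1.99e-03	6.13e-08
rs6892109	5	C	T	.	2.7	1.73	4.22	1.34e-05	2.09	1.26	3.46	4.39e-03	9.90e-08
chr12:121988899	12	C	T	.	2.38	1.62	3.48	8.52e-06	1.69	1.14	2.51	9.73e-03	1.42e-07
rs12658947	5	A	G	.	2.69	1.72	4.2	1.51e-05	2.01	1.21	3.34	6.71e-03	1.69e-07
rs12659412	5	T	C	.	2.69	1.72	4.2	1.51e-05	2.01	1.21	3.34	6.71e-03	1.69e-07
rs509061	1	T	C	SPRR2G	2.08	1.5	2.89	1.28e-05	1.72	1.15	2.59	8.50e-03	1.82e-07
rs2052548	5	A	C	.	2.73	1.74	4.27	1.18e-05	1.93	1.17	3.2	1.02e-02	2.03e-07
rs72755734	5	A	G	.	2.72	1.74	4.26	1.22e-05	1.93	1.17	3.2	1.02e-02	2.09e-07
rs1477347	5	G	A	.	2.71	1.73	4.24	1.31e-05	1.93	1.17	3.2	1.02e-02	2.24e-07
chr12:121973317	12	G	A	.	2.30	1.58	3.35	1.45e-05	1.67	1.13	2.49	1.06e-02	2.57e-07
rs72755727	5	A	T	.	2.67	1.71	4.17	1.72e-05	1.94	1.17	3.21	1.00e-02	2.84e-07
rs77668680	1	C	CAG	SPRR2G	2.23	1.58	3.14	4.23e-06	1.54	1.02	2.33	4.16e-02	3.81e-07
rs6500715	16	G	C	RBFOX1	0.47	0.34	0.65	5.51e-06	0.69	0.49	0.97	3.54e-02	3.96e-07
rs34338452	8	AT	A	SAMD12	2.24	1.57	3.19	7.58e-06	1.59	1.05	2.39	2.78e-02	3.99e-07
rs10094604	8	G	T	SAMD12	2.28	1.6	3.24	4.73e-06	1.53	1.02	2.29	4.07e-02	4.09e-07
rs524887	1	A	G	SAMD13	2.23	1.58	3.14	4.57e-06	1.53	1.01	2.31	2.70e-02	3.99e-07
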