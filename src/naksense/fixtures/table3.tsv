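no	category	direction	gene	rvsmc_ouabain	rvsmc_ouabain_se	rvsmc_kfree	rvsmc_kfree_se	huvec_ouabain	huvec_ouabain_se	huvec_kfree	huvec_kfree_se	hela_ouabain	hela_ouabain_se	hela_kfree	hela_kfree_se
1	t	up	Egr1	4.80	0.18	6.97	0.18	9.69	0.15	64.81	0.12	13.78	0.15	46.85	0.09
2	t	up	Fos	3.17	0.08	8.76	0.08	2.60	0.09	15.97	0.11	5.88	0.13	41.93	0.09
3	t	up	Fosb	5.91	0.11	15.22	0.12	1.99	0.08	5.82	0.10	3.12	0.16	23.85	0.11
4	t	up	Atf3	4.72	0.03	20.63	0.08	1.86	0.05	7.50	0.05	2.28	0.10	11.29	0.05
5	t	up	Zfp36	3.52	0.10	5.95	0.09	2.36	0.10	12.07	0.11	2.27	0.04	10.30	0.10
6	t	up	Jun	1.28	0.06	1.62	0.07	1.94	0.06	5.11	0.05	1.91	0.11	8.03	0.04
7	i	up	Il6	3.40	0.14	4.76	0.15	1.44	0.09	2.12	0.08	2.01	0.11	8.01	0.08
8	d	up	Ppp1r15a	2.59	0.12	3.57	0.09	2.54	0.10	4.08	0.10	2.98	0.16	7.73	0.14
9	d	up	Dusp8	1.55	0.11	3.09	0.12	1.54	0.08	3.35	0.06	1.83	0.11	6.25	0.10
10	t	up	Ddit3	2.15	0.03	4.26	0.03	1.35	0.09	4.91	0.09	1.52	0.13	5.46	0.10
11	t	up	Junb	4.03	0.08	4.24	0.07	1.85	0.09	7.32	0.07	2.20	0.09	5.40	0.08
12	i	up	Ptgs2	9.46	0.10	9.95	0.11	3.73	0.03	7.84	0.04	2.39	0.13	5.15	0.10
13	t	up	Cyr61	1.71	0.09	2.00	0.10	1.34	0.04	2.11	0.04	2.02	0.09	5.11	0.08
14	t	up	Nr4a2	5.19	0.07	8.65	0.12	2.03	0.09	3.94	0.10	2.39	0.07	4.76	0.05
15	i	up	Nfkbiz	3.24	0.09	4.47	0.08	2.44	0.06	5.15	0.02	2.11	0.07	4.66	0.07
16	t	up	Hes1	3.00	0.06	6.15	0.09	2.07	0.09	5.86	0.08	1.71	0.10	4.62	0.11
17	d	up	Spry4	1.84	0.06	1.40	0.09	3.27	0.12	4.91	0.12	2.12	0.17	4.26	0.17
18	o	up	Txnip	3.85	0.10	5.84	0.10	2.62	0.09	6.99	0.12	3.07	0.10	4.18	0.09
19	d	up	Areg	1.90	0.04	1.75	0.06	1.36	0.11	1.39	0.07	1.93	0.13	4.13	0.14
20	i	up	Nfkbia	2.46	0.03	5.80	0.05	1.39	0.09	2.68	0.08	1.54	0.10	3.63	0.10
21	t	up	Klf10	2.80	0.05	3.66	0.06	1.83	0.07	4.53	0.05	1.74	0.06	3.57	0.05
22	d	up	Plk3	3.29	0.12	3.64	0.12	1.22	0.06	2.15	0.06	1.41	0.05	2.83	0.07
23	d	up	Ccnl1	2.10	0.06	3.82	0.08	1.62	0.05	2.73	0.04	1.33	0.09	2.72	0.08
24	d	up	Abl2	1.96	0.11	2.02	0.08	1.44	0.06	2.04	0.05	1.74	0.07	2.62	0.05
25	d	up	Pmaip1	1.46	0.06	1.64	0.05	1.51	0.11	2.30	0.11	1.71	0.08	2.55	0.06
26	t	up	Bcl6	1.64	0.10	1.88	0.09	1.89	0.07	3.78	0.07	1.32	0.10	2.53	0.10
27	t	up	Mafk	2.94	0.08	3.19	0.11	1.37	0.08	1.23	0.08	1.59	0.07	2.50	0.07
28	d	up	Errfi1	3.14	0.07	2.59	0.10	1.75	0.07	3.06	0.07	1.45	0.05	2.42	0.06
29	o	up	Dusp16	2.33	0.08	2.47	0.09	1.62	0.09	3.49	0.08	1.46	0.11	2.38	0.11
30	t	up	Maff	2.47	0.07	3.11	0.09	1.27	0.09	2.25	0.04	1.42	0.10	2.35	0.10
31	t	up	Tsc22d2	1.21	0.04	1.76	0.06	1.80	0.05	3.80	0.03	1.41	0.05	2.24	0.05
32	o	up	Slc25a25	2.18	0.03	3.56	0.05	1.77	0.06	2.97	0.05	1.49	0.05	2.23	0.07
33	o	up	Insig1	1.93	0.08	1.96	0.09	1.36	0.04	1.86	0.03	1.67	0.06	2.23	0.05
34	t	up	Mxd1	1.83	0.06	3.21	0.05	1.49	0.07	2.42	0.06	1.66	0.08	2.19	0.08
35	t	up	Fosl1	1.92	0.07	2.17	0.07	1.29	0.04	2.35	0.04	1.20	0.04	2.17	0.06
36	d	up	Hbegf	4.44	0.14	4.10	0.18	1.52	0.06	2.25	0.03	1.35	0.07	2.13	0.08
37	d	up	Epha2	3.61	0.08	2.98	0.12	1.31	0.07	1.41	0.06	1.39	0.11	2.11	0.08
38	d	up	Birc3	3.30	0.03	7.47	0.03	1.69	0.09	4.58	0.12	1.29	0.09	2.04	0.09
39	d	up	Efna1	1.82	0.04	1.26	0.03	1.48	0.04	1.83	0.05	1.34	0.09	2.02	0.09
40	t	up	Zc3h12c	1.39	0.06	1.70	0.02	1.76	0.09	1.62	0.09	1.68	0.08	2.01	0.07
41	o	up	Ldlr	1.50	0.04	1.51	0.04	1.48	0.05	1.86	0.05	1.75	0.03	1.95	0.04
42	t	up	Sertad2	1.74	0.06	1.60	0.07	1.36	0.08	1.79	0.07	1.29	0.09	1.93	0.07
43	t	up	Zc3h12a	2.14	0.06	2.25	0.08	1.35	0.06	2.68	0.07	1.25	0.05	1.92	0.03
44	t	up	Cpeb4	2.46	0.04	2.59	0.05	1.26	0.06	1.74	0.07	1.31	0.06	1.87	0.05
45	i	up	Il1rap	1.32	0.09	1.21	0.06	1.33	0.10	1.99	0.10	1.42	0.09	1.71	0.07
46	f	up	Dnajb9	1.33	0.03	1.30	0.03	1.63	0.05	2.20	0.06	1.46	0.07	1.67	0.10
47	t	up	Ppp1r15b	1.72	0.02	1.77	0.02	1.30	0.05	1.63	0.03	1.35	0.04	1.66	0.03
48	d	up	Dusp6	3.36	0.10	1.73	0.11	1.47	0.12	1.81	0.09	1.48	0.07	1.64	0.07
49	d	up	Zswim6	1.44	0.03	1.70	0.04	1.22	0.03	1.64	0.03	1.35	0.02	1.62	0.03
50	t	up	Zbtb43	1.34	0.05	2.14	0.05	1.24	0.06	1.76	0.08	1.39	0.05	1.59	0.05
51	o	up	Slc20a1	1.56	0.04	1.29	0.04	1.30	0.03	1.43	0.04	1.29	0.04	1.56	0.04
52	o	up	Hmgcs1	1.80	0.03	2.01	0.03	1.24	0.02	1.56	0.01	1.38	0.04	1.44	0.03
53	f	up	Coq10b	1.71	0.03	1.47	0.03	1.22	0.04	1.47	0.05	1.41	0.05	1.43	0.06
54	t	up	Clk1	1.37	0.07	2.14	0.07	1.40	0.07	1.66	0.07	1.41	0.06	1.40	0.07
55	t	up	Zbtb11	2.16	0.05	2.00	0.08	1.42	0.05	1.51	0.05	1.31	0.04	1.36	0.05
56	t	up	Nr1d1	1.57	0.05	1.74	0.08	1.43	0.10	1.48	0.07	1.50	0.07	1.31	0.09
57	o	up	Stard4	1.30	0.05	1.51	0.05	1.32	0.06	1.46	0.03	1.39	0.07	1.30	0.05
58	t	up	Nfya	1.52	0.06	1.45	0.09	1.49	0.04	1.48	0.04	1.41	0.05	1.30	0.04
59	t	up	Jmjd1c	1.49	0.03	1.59	0.05	1.39	0.03	1.52	0.05	1.28	0.04	1.29	0.05
60	t	up	Dcp1a	1.66	0.02	1.65	0.06	1.24	0.03	1.26	0.03	1.27	0.06	1.28	0.04
61	t	up	E2f3	1.26	0.06	1.43	0.05	1.41	0.08	1.73	0.08	1.22	0.06	1.27	0.04
1	o	down	Gabre	-1.21	0.08	-1.45	0.06	-1.33	0.06	-1.48	0.03	-2.01	0.09	-3.15	0.14
2	t	down	Hoxb5	-2.25	0.12	-2.82	0.13	-1.75	0.06	-3.00	0.08	-1.49	0.08	-2.35	0.09
3	t	down	Znf250	-1.26	0.07	-1.20	0.08	-1.62	0.06	-1.90	0.05	-1.72	0.07	-2.08	0.06
4	t	down	Rpp40	-1.70	0.08	-1.84	0.05	-1.41	0.03	-1.79	0.06	-1.27	0.05	-2.03	0.06
5	t	down	Rbm45	-1.33	0.05	-1.37	0.05	-1.41	0.06	-1.67	0.05	-1.48	0.11	-1.89	0.08
6	d	down	Aggf1	-1.54	0.04	-1.24	0.06	-1.30	0.08	-1.29	0.08	-1.54	0.07	-1.83	0.06
7	d	down	Fancf	-1.51	0.07	-1.30	0.06	-1.85	0.08	-1.71	0.07	-1.48	0.10	-1.83	0.09
8	o	down	Rhobtb1	-1.98	0.06	-1.35	0.06	-1.41	0.08	-1.48	0.08	-1.34	0.11	-1.80	0.07
9	t	down	Znf691	-1.42	0.09	-1.33	0.07	-1.28	0.08	-1.23	0.07	-1.46	0.11	-1.67	0.06
10	o	down	Rrs1	-1.26	0.07	-1.39	0.10	-1.31	0.08	-1.33	0.07	-1.29	0.03	-1.59	0.03
11	t	down	Mrpl46	-1.34	0.04	-1.24	0.05	-1.21	0.04	-1.34	0.03	-1.24	0.05	-1.58	0.07
12	o	down	Golga5	-1.65	0.04	-1.21	0.06	-1.38	0.05	-1.48	0.05	-1.29	0.05	-1.56	0.04
13	d	down	Psrc1	-1.65	0.08	-1.80	0.07	-1.25	0.08	-1.44	0.05	-1.23	0.04	-1.53	0.05
14	o	down	Spata7	-1.55	0.07	-1.32	0.06	-1.29	0.06	-1.31	0.06	-1.38	0.08	-1.49	0.08
15	d	down	Tgfbrap1	-1.49	0.06	-1.22	0.05	-1.36	0.05	-1.55	0.03	-1.29	0.06	-1.47	0.05
16	o	down	Hps6	-2.15	0.07	-1.69	0.10	-1.39	0.09	-1.31	0.10	-1.48	0.08	-1.46	0.06
17	t	down	Znf184	-1.78	0.06	-1.55	0.08	-1.71	0.10	-2.01	0.08	-1.28	0.07	-1.44	0.06
18	t	down	Pars2	-1.61	0.04	-1.20	0.05	-1.28	0.05	-1.28	0.06	-1.38	0.05	-1.34	0.04
19	o	down	Sh3bp5l	-1.82	0.04	-1.54	0.03	-1.46	0.07	-1.40	0.09	-1.35	0.07	-1.27	0.07
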