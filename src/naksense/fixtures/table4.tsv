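gene	affy_id	ouabain_fold	ouabain_p	kfree_fold	kfree_p	other_cells
EGR1	8108370	13.78	7.27E-08	46.85	8.18E-05
FOS	7975779	5.88	7.27E-08	41.93	8.56E-06
FOSB	8029693	3.12	2.78E-07	23.85	1.51E-05
NR4A1	7955589	2.63	1.39E-07	11.79	8.56E-06	3.52/10.73 (HUVEC)
TNFAIP3	8122265	1.90	2.27E-07	11.77	8.56E-06	3.34/15.71 (HUVEC)
ATF3	7909610	2.28	9.86E-08	11.29	8.56E-06
EDN1	8116921	2.31	2.55E-06	11.15	1.10E-04
NR4A3	8156848	2.77	8.28E-08	11.06	8.56E-06	4.16/4.68 (HUVEC)
ZFP36	8028652	2.27	9.86E-08	10.30	8.56E-06
IL8	8095680	2.93	5.07E-06	10.00	5.31E-04	1.96/4.45 (HUVEC)
JUN	7916609	1.91	1.68E-07	8.03	8.56E-06
IL6	8131803	2.01	3.12E-07	8.01	1.51E-05
PPP1R15A	8030128	2.98	2.08E-06	7.73	5.19E-04
DUSP8	7945641	1.83	4.85E-07	6.25	2.05E-05
EGR2	7933872	1.85	1.39E-06	5.79	6.41E-05	2.87/9.08 (RVSMC)
DDIT3	7964460	1.52	2.19E-06	5.46	4.39E-05
JUNB	8026047	2.20	5.35E-07	5.40	7.13E-05
PTGS2	7922976	2.39	4.30E-06	5.15	9.30E-04
CYR61	7902687	2.02	2.78E-07	5.11	2.71E-05
CSRNP1	8086330	2.32	2.88E-06	4.80	7.31E-04
HIST1H3J	8124537	1.69	2.25E-05	4.77	6.25E-04	1.40/1.62 (HUVEC)
NR4A2	8055952	2.39	1.39E-07	4.76	4.04E-05
NFKBIZ	8081386	2.11	3.12E-07	4.66	5.06E-05
AREG	8095744	2.10	2.01E-05	4.64	2.04E-03
DUSP1	8115831	2.24	1.60E-07	4.64	4.09E-05	1.59/3.81 (HUVEC)
HES1	8084880	1.71	1.05E-06	4.62	4.57E-05
SPRY4	8114797	2.12	3.80E-05	4.26	5.65E-03
TXNIP	7904726	3.07	6.87E-07	4.18	1.03E-02
DUSP10	7924450	1.88	3.99E-07	4.04	4.71E-05	1.32/3.02 (HUVEC)
CDKN2AIP	8098500	1.84	2.19E-06	4.01	2.10E-04	1.26/2.05 (HUVEC)
ID2	8040103	1.64	2.91E-06	4.01	1.25E-04
LOC100287934	7909990	-2.41	2.12E-03	-4.01	3.18E-05	-1.96/-4.68 (HUVEC)
LOC100131860	7991047	-2.47	3.26E-03	-4.73	3.32E-05
TRIM52	8110666	-1.57	6.01E-03	-5.03	8.88E-07	-1.64/-3.85 (HUVEC)
C9orf3	8156571	-2.85	4.40E-05	-7.96	1.39E-07	-1.71/-2.24 (HUVEC)
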