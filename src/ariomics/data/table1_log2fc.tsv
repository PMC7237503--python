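gene	protein	log2fc_2D_Bicalut	log2fc_2D_Apalut	log2fc_2D_Enzalut	log2fc_3D_Bicalut	log2fc_3D_Apalut	log2fc_3D_Enzalut
SQRDL	Sulphide:quinone oxidoreductase, mitochondrial	4.10	5.01	4.87	2.12	3.14	3.30
EPHX1	Epoxide hydrolase 1	1.31	1.81	2.55	0.78	2.29	2.62
ATP1B1	Sodium/potassium-transporting ATPase subunit beta-1	0.96	2.22	2.40	1.17	1.77	1.26
ALDH3A2	Fatty aldehyde dehydrogenase	2.41	1.47	2.05	0.74	0.93	1.33
DECR1	2,4-dienoyl-CoA reductase, mitochondrial	1.08	1.73	1.28	1.23	1.76	1.09
TST	Thiosulfate sulfurtransferase	1.33	1.00	1.85	0.99	0.80	0.95
FOLH1	Glutamate carboxypeptidase 2	0.59	1.04	1.17	0.61	1.41	0.87
USP5	Ubiquitin carboxyl-terminal hydrolase 5	0.87	0.81	1.37	0.81	0.85	0.66
NASP	Nuclear autoantigenic sperm protein	-1.05	-1.41	-1.34	-0.72	-0.99	-0.75
VTA1	Vacuolar protein sorting-associated protein VTA1 homologue	-1.24	-1.30	-1.42	-0.88	-0.82	-1.34
TPT1	Translationally-controlled tumour protein	-1.35	-1.81	-2.26	-1.29	-1.15	-2.40
PDLIM5	PDZ and LIM domain protein 5	-2.66	-2.27	-2.98	-2.71	-3.00	-3.36
KLK3	Prostate-specific antigen	-2.63	-2.83	-2.45	-4.39	-3.79	-3.61
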