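protein	pdb	group	localization	trans_minus	trans_plus	cis_minus	cis_plus	inhibitor	inhibitor_score
COX2	5IKR	anti_apoptosis_survival	cytoplasm	-10.60	-9.68	-9.62	-10.57	Sorafenib	-9.06
Hsp70	3ATV	anti_apoptosis_survival	cytoplasm	-8.93	-7.84	-8.43	-9.03	Apoptozole	-8.24
Hsp90a	3O0I	anti_apoptosis_survival	cytoplasm	-10.60	-10.09	-10.43	-10.77	Pu-H54	-9.43
Hsp90b	3NMQ	anti_apoptosis_survival	cytoplasm	-10.80	-9.28	-10.63	-9.74	EC44	-10.20
PAK6	4KS8	anti_apoptosis_survival	cytoplasm	-8.55	-7.56	-8.09	-8.39	Sunitinib	-7.50
Survivin	1F3H	anti_apoptosis_survival	cytoplasm	-8.78	-8.63	-8.76	-8.13	YM155	-7.25
XIAP	5OQW	anti_apoptosis_survival	cytoplasm	-7.67	-6.74	-7.70	-7.49	A4E	-10.66
cMyc	6G6J	cell_growth_proliferation	nucleus	-7.30	-6.32	-7.22	-6.55	MYCi975	-6.19
CDK2	4J52	cell_growth_proliferation	nucleus	-9.74	-9.14	-9.90	-9.90	Dinaciclib	-8.93
PLK1	4OYA	cell_growth_proliferation	nucleus	-8.87	-8.87	-8.92	-8.84	Pyrimidodiazepinone	-5.92
ADC10	1C25	cell_growth_proliferation	cytoplasm	-12.59	-11.32	-12.21	-12.12	SQ-22536	-8.23
AR	1CWT	cell_growth_proliferation	cytoplasm	-8.50	-8.35	-9.36	-9.03	(R)-Bicalutamide	-8.55
cdc25A	4Y72	cell_growth_proliferation	cytoplasm	-9.19	-7.14	-7.98	-8.97	Quinonoid	-6.90
cdc25B	1FVV	cell_growth_proliferation	cytoplasm	-7.62	-7.46	-7.63	-7.78	Quinonoid	-6.91
CDK1	6P8E	cell_growth_proliferation	cytoplasm	-10.34	-9.27	-9.79	-9.69	CGP74514A	-10.96
CDK4	1FVV	cell_growth_proliferation	cytoplasm	-8.16	-7.22	-7.32	-7.55	Palbociclib	-9.03
cyclinA	4Y72	cell_growth_proliferation	cytoplasm	-8.89	-9.56	-8.92	-8.69	ligand 107	-9.76
cyclinB1	6P8E	cell_growth_proliferation	cytoplasm	-10.45	-10.08	-10.24	-10.84	Q27097368	-9.40
cyclinD1	1L09	cell_growth_proliferation	cytoplasm	-8.18	-7.04	-8.20	-8.42	Fascaplysin	-7.57
ER	1SJ0	cell_growth_proliferation	cytoplasm	-8.96	-8.43	-9.02	-8.87	E4D	-11.74
GSK3b	4JSV	cell_growth_proliferation	cytoplasm	-10.64	-10.01	-9.91	-10.05	Tideglusib	-8.59
mTOR	4UJA	cell_growth_proliferation	cytoplasm	-9.12	-8.46	-9.09	-8.95	AZD8055	-10.21
PKA	3IW4	cell_growth_proliferation	cytoplasm	-9.48	-8.46	-9.58	-9.61	AT13148	-12.83
PKC	3LLU	cell_growth_proliferation	cytoplasm	-9.83	-8.99	-9.87	-9.79	Enzastaurin	-12.69
RagC	4R7H	cell_growth_proliferation	cytoplasm	-9.21	-8.73	-8.95	-8.82	Palomid-529	-8.85
CSF1R	4HJO	cell_growth_proliferation	membrane	-11.84	-9.29	-10.53	-10.40	Pexidartinib	-11.59
EGFR	5X02	cell_growth_proliferation	membrane	-9.71	-6.45	-9.69	-7.14	Erlotinib	-8.82
FLT3	1N26	cell_growth_proliferation	membrane	-9.24	-8.76	-9.11	-9.13	Gilteritinib	-9.64
IL6R	6G6J	cell_growth_proliferation	membrane	-7.74	-7.48	-7.61	-7.73	Terminolic acid	-7.11
cFos	1FOS	metastasis	nucleus	-5.63	-5.07	-5.32	-5.51	T-5224	-6.20
cJun	1FOS	metastasis	nucleus	-5.66	-4.95	-5.27	-5.51	T-5224	-7.72
mmp12	4XCT	metastasis	nucleus	-11.19	-10.23	-10.71	-10.80	BAY-7598	-12.47
mmp9	5LAB	metastasis	nucleus	-10.41	-10.48	-10.37	-9.64	ARP101	-12.27
snail	3W5K	metastasis	nucleus	-7.85	-7.53	-7.49	-7.47	Chembl4517265	-7.70
AKR1B1	4JIR	metastasis	cytoplasm	-11.32	-11.15	-11.46	-11.59	Epalrestat	-10.14
ALP	2GLQ	metastasis	cytoplasm	-7.26	-7.95	-7.36	-7.34	Levamisole	-6.08
PALP	3MK0	metastasis	cytoplasm	-6.92	-6.77	-7.69	-7.48	Levamisole	-5.79
TGFBR1	1E3G	metastasis	membrane	-7.08	-6.92	-7.06	-7.62	SB431542	-7.17
TGFBR2	2PJY	metastasis	membrane	-7.96	-7.73	-7.88	-8.21	J2V	-7.10
AKT	1GZN	signaling	cytoplasm	-9.64	-8.97	-9.12	-9.23	Capivasertib	-8.50
CRAF	3OMV	signaling	cytoplasm	-8.60	-8.11	-9.14	-8.82	Sorafenib	-9.06
ERK1	4QTB	signaling	cytoplasm	-9.63	-9.24	-9.54	-9.65	SCH772984	-12.96
ERK2	5BUJ	signaling	cytoplasm	-9.15	-8.65	-9.11	-9.42	Q27455064	-8.39
Grb2	1GRI	signaling	cytoplasm	-8.03	-7.32	-7.78	-7.92	CGP-78850	-7.88
IKK	4KIK	signaling	cytoplasm	-7.89	-7.70	-7.80	-8.18	Dehydrocostus Lactone	-7.28
JAK1	5HX8	signaling	cytoplasm	-8.64	-8.56	-8.60	-8.44	66P	-10.52
JAK2	3KRR	signaling	cytoplasm	-8.20	-7.66	-8.40	-8.17	NVP-BSK805	-11.22
JAK3	5TTV	signaling	cytoplasm	-8.97	-8.62	-9.03	-8.81	Inhibitor 6	-7.30
K-RAS	4M1W	signaling	cytoplasm	-7.55	-7.19	-7.85	-7.69	Sotorasib	-7.11
MEK1	2P55	signaling	cytoplasm	-10.34	-9.48	-10.63	-10.14	Trametinib	-13.05
MEK2	1S9I	signaling	cytoplasm	-10.17	-9.41	-10.95	-10.06	Trametinib	-12.17
MNK2	6JLR	signaling	cytoplasm	-9.86	-9.60	-10.02	-9.94	BV9	-8.64
p38	4MYG	signaling	cytoplasm	-8.73	-7.89	-8.63	-8.61	PD169316	-7.94
PI3K	3CSF	signaling	cytoplasm	-9.47	-8.66	-9.12	-9.06	Apitolisib	-9.55
PIM1	1YXV	signaling	cytoplasm	-9.38	-8.03	-9.16	-9.30	6SD	-6.95
RAC1	1HH4	signaling	cytoplasm	-10.12	-9.33	-9.36	-10.12	NSC-23766	-6.94
SMAD3	1MK2	signaling	cytoplasm	-8.33	-7.78	-8.06	-7.91	SIS3	-9.05
STAT1	1YVL	signaling	cytoplasm	-7.41	-7.75	-7.49	-7.37	Fludarabine	-5.41
STAT3	6TLC	signaling	cytoplasm	-7.84	-7.51	-7.63	-7.82	STAT3-IN-3	-9.87
STAT5	6MBZ	signaling	cytoplasm	-9.52	-9.27	-8.78	-8.96	IN-2	-8.45
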