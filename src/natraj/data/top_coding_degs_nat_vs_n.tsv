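gene_id	symbol	padj	fold_change	in_ltneg_deg_list
ENSG00000213977.7	TAX1BP3	2.43E-12	3.67	yes
ENSG00000147586.9	MRPS28	4.97E-11	2.39	yes
ENSG00000257727.5	CNPY2	1.34E-08	2.21	yes
ENSG00000148180.18	GSN	2.1E-08	3.82	yes
ENSG00000174903.15	RAB1B	4.09E-08	-1.59	yes
ENSG00000203791.14	METTL10	4.15E-08	1.93	yes
ENSG00000170296.9	GABARAP	8.02E-08	4.17	yes
ENSG00000143368.9	SF3B4	7.59E-07	-1.56	yes
ENSG00000136371.10	MTHFS	2.29E-06	2.42	yes
ENSG00000171295.12	ZNF440	2.73E-06	1.53	no
ENSG00000088038.17	CNOT3	4.31E-06	-2.16	yes
ENSG00000132471.11	WBP2	6.74E-06	-1.62	yes
ENSG00000277203.1	F8A1	8.99E-06	-1.75	yes
ENSG00000183889.12	AC138969.4	1.44E-05	-1.84	yes
ENSG00000198171.12	DDRGK1	1.87E-05	-1.54	yes
ENSG00000128739.21	SNRPN	2.59E-05	2.29	yes
ENSG00000104969.9	SGTA	2.76E-05	-1.51	yes
ENSG00000263290.5	SCAMP3	3.07E-05	-1.58	yes
ENSG00000164039.14	BDH2	3.16E-05	1.71	yes
ENSG00000147955.16	SIGMAR1	3.26E-05	-1.56	yes
ENSG00000175274.18	TP53I11	5.42E-05	-1.74	yes
ENSG00000270011.6	ZNF559-ZNF177	5.71E-05	2.80	yes
ENSG00000205544.3	TMEM256	6.32E-05	3.71	yes
ENSG00000111775.2	COX6A1	6.36E-05	2.28	yes
ENSG00000100350.14	FOXRED2	6.66E-05	-1.87	yes
ENSG00000279576.1	AP000769.1	8.82E-05	16.16	yes
ENSG00000181264.8	TMEM136	9.61E-05	1.54	yes
ENSG00000115239.21	ASB3	9.75E-05	1.69	yes
ENSG00000100348.9	TXN2	0.000123	-1.57	yes
ENSG00000167182.13	SP2	0.000132	-1.82	yes
ENSG00000277462.1	ZNF670	0.000133	2.05	yes
ENSG00000167644.11	C19orf33	0.000162	19.70	yes
ENSG00000134590.13	FAM127A	0.000174	-1.62	yes
ENSG00000239697.10	TNFSF12	0.000177	-1.83	yes
ENSG00000164898.12	C7orf55	0.000191	3.25	yes
ENSG00000124614.13	RPS10	0.000237	13.41	yes
ENSG00000188257.10	PLA2G2A	0.000277	-14.64	yes
ENSG00000196757.7	ZNF700	0.000284	1.59	yes
ENSG00000116649.9	SRM	0.000299	-1.83	yes
ENSG00000189171.14	S100A13	0.000328	1.93	yes
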