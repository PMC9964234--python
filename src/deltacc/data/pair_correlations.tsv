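# Gene-pair Pearson correlations reported for the ten-astronaut spaceflight
# study (accession E-GEOD-74708): pairs with |CC_in - CC_pre| >= 0.70 within
# each of the top enriched pathways, as printed to two decimals in the study
# report. dcc_printed is the published differential; for ACSL4-GPT it is
# internally inconsistent with cc_in - cc_pre (1.61 vs 1.51), a known typo.
pathway	gene_a	gene_b	cc_pre	cc_in	dcc_printed
Signal transduction	ARHGAP9	COL4A4	-0.51	0.28	0.79
Signal transduction	ARHGAP9	THBS3	0.39	-0.48	-0.87
Signal transduction	CCL2	COL4A4	-0.95	-0.07	0.88
Signal transduction	CCL2	CREB1	0.93	-0.09	-1.02
Signal transduction	CCL2	CRHR1	0.68	-0.11	-0.79
Signal transduction	CCL2	THBS3	0.68	-0.19	-0.87
Signal transduction	CCNC	COL4A4	0.46	-0.65	-1.11
Signal transduction	CCNC	CRHR1	-0.58	0.65	1.23
Signal transduction	CCNC	THBS3	-0.41	0.34	0.75
Signal transduction	CHN1	CRHR1	0.43	-0.59	-1.02
Signal transduction	CHN1	HIF1A	-0.36	0.34	0.70
Signal transduction	COL4A4	CREB1	-0.93	-0.03	0.90
Signal transduction	COL4A4	NFATC1	-0.77	0.50	1.27
Signal transduction	COL4A4	PDPK1	0.41	-0.50	-0.91
Signal transduction	CREB1	CRHR1	0.80	-0.03	-0.83
Signal transduction	CREB1	THBS3	0.79	0.05	-0.74
Signal transduction	CRHR1	KIDINS220	0.59	-0.14	-0.73
Signal transduction	CRHR1	NFATC1	0.83	-0.47	-1.30
Signal transduction	CRHR1	PDPK1	-0.57	0.34	0.91
Signal transduction	CRHR1	YES1	0.40	-0.71	-1.11
Signal transduction	CTNNBIP1	NFATC1	0.07	0.85	0.78
Signal transduction	KIDINS220	PDPK1	-0.74	0.30	1.04
Signal transduction	KIDINS220	SOS2	-0.86	0.29	1.15
Signal transduction	KIDINS220	YES1	0.70	0.00	-0.70
Signal transduction	NFATC1	THBS3	0.72	-0.34	-1.06
Signal transduction	PDPK1	SOS2	0.63	-0.22	-0.85
Signal transduction	SOS2	YES1	-0.61	0.17	0.78
Immune system	ATF2	NFATC1	-0.03	-0.75	-0.72
Immune system	BIRC2	PDPK1	-0.73	0.13	0.86
Immune system	CREB1	EIF4E2	-0.94	0.07	1.01
Immune system	CREB1	IL7	0.91	-0.03	-0.94
Immune system	CREB1	UBR4	0.90	-0.28	-1.18
Immune system	CREB1	XAF1	0.71	-0.03	-0.74
Immune system	EIF4E2	IL7	-0.87	0.10	0.97
Immune system	EIF4E2	NFATC1	-0.87	0.46	1.33
Immune system	EIF4E2	UBR4	-0.95	0.40	1.35
Immune system	EIF4E2	XAF1	-0.72	0.10	0.82
Immune system	IL7	UBR4	0.88	-0.34	-1.22
Immune system	NFATC1	UBR4	0.85	-0.18	-1.03
Immune system	PDPK1	UBR4	-0.55	0.34	0.89
Immune system	UBA5	UBR4	0.59	-0.27	-0.86
Immune system	UBR4	XAF1	0.88	-0.16	-1.04
Immune system	UBR4	YES1	0.35	-0.59	-0.94
Gene expression	AARS2	ZNF253	-0.57	0.23	0.80
Gene expression	AARS2	ZNF606	-0.91	0.21	1.12
Gene expression	AARS2	ZNF711	-0.60	0.31	0.91
Gene expression	RRN3	ZNF184	-0.51	0.34	0.85
Gene expression	RRN3	ZNF606	-0.06	0.87	0.93
Gene expression	RRN3	ZNF711	-0.22	0.50	0.72
Metabolism	ACSL4	ARSK	0.56	-0.66	-1.22
Metabolism	ACSL4	CCNC	0.75	-0.74	-1.49
Metabolism	ACSL4	GPT	-0.66	0.85	1.61
Metabolism	ACSL4	NDUFA1	0.81	0.05	-0.76
Metabolism	ACSL4	PIKFYVE	-0.22	0.69	0.91
Metabolism	ARSK	GM2A	0.48	-0.34	-0.82
Metabolism	CCNC	GM2A	0.65	-0.44	-1.09
Metabolism	CCNC	PSAT1	0.88	-0.23	-1.11
Metabolism	GPT	NDUFA1	-0.59	0.24	0.83
Metabolism	GPT	PIKFYVE	-0.05	0.79	0.84
Metabolism	GPT	PSAT1	-0.65	0.46	1.11
Metabolism of proteins	ARSK	DPP4	-0.27	0.57	0.84
Metabolism of proteins	CCL2	DPP4	0.79	-0.26	-1.05
Metabolism of proteins	CCL2	PCSK1	0.90	-0.16	-1.06
Metabolism of proteins	CCL2	SPON2	0.77	-0.03	-0.80
Metabolism of proteins	DPP4	GNE	0.74	-0.21	-0.95
Metabolism of proteins	DPP4	MAGT1	-0.57	0.37	0.94
Metabolism of proteins	MAGT1	PCSK1	-0.85	0.21	1.06
Metabolism of proteins	PCSK1	SPON2	0.84	0.01	-0.83
Developmental biology	CCNC	COL4A4	0.46	-0.65	-1.11
Developmental biology	CLTB	SCN2B	-0.39	0.37	0.76
Developmental biology	COL4A4	CREB1	-0.93	-0.03	0.90
Developmental biology	SOS2	YES1	-0.61	0.17	0.78
Metabolism of lipids and lipoproteins	ACSL4	ARSK	0.56	-0.66	-1.22
Metabolism of lipids and lipoproteins	ACSL4	CCNC	0.75	-0.74	-1.49
Metabolism of lipids and lipoproteins	ACSL4	PIKFYVE	-0.22	0.69	0.91
Metabolism of lipids and lipoproteins	ARSK	GM2A	0.48	-0.34	-0.82
Metabolism of lipids and lipoproteins	CCNC	GM2A	0.65	-0.44	-1.09
Axon guidance	CLTB	SCN2B	-0.39	0.37	0.76
Axon guidance	COL4A4	CREB1	-0.93	-0.03	0.90
Axon guidance	SOS2	YES1	-0.61	0.17	0.78
Innate immune system	ATF2	NFATC1	-0.03	-0.75	-0.72
Innate immune system	BIRC2	PDPK1	-0.73	0.13	0.86
Disease	CCNC	CHMP4C	0.60	-0.38	-0.98
Disease	CHMP4C	CREB1	-0.85	0.31	1.16
Disease	CHMP4C	PDPK1	0.44	-0.63	-1.07
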