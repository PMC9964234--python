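Signal transduction	DEGs of the top enriched pathways, ten-astronaut spaceflight study (E-GEOD-74708)	ARHGAP9	CCL2	CCNC	CHN1	CLTB	COL4A4	CREB1	CRHR1	CTNNBIP1	HIF1A	KIDINS220	NFATC1	PDPK1	SOS2	THBS3	YES1
Immune system	DEGs of the top enriched pathways, ten-astronaut spaceflight study (E-GEOD-74708)	ATF2	BIRC2	CREB1	EIF4E2	IL7	NFATC1	PDPK1	UBA5	UBR4	XAF1	YES1
Gene expression	DEGs of the top enriched pathways, ten-astronaut spaceflight study (E-GEOD-74708)	AARS2	CCNC	RRN3	ZNF184	ZNF253	ZNF529	ZNF606	ZNF664	ZNF699	ZNF711
Metabolism	DEGs of the top enriched pathways, ten-astronaut spaceflight study (E-GEOD-74708)	ACSL4	ARSK	CCNC	GM2A	GPT	HACL1	NDUFA1	PIKFYVE	PSAT1
Metabolism of proteins	DEGs of the top enriched pathways, ten-astronaut spaceflight study (E-GEOD-74708)	ARSK	CCL2	DPP4	GNE	MAGT1	PCSK1	SPON2	XRN2
Generic transcription pathway	DEGs of the top enriched pathways, ten-astronaut spaceflight study (E-GEOD-74708)	CCNC	ZNF184	ZNF253	ZNF529	ZNF606	ZNF664	ZNF699	ZNF711
Developmental biology	DEGs of the top enriched pathways, ten-astronaut spaceflight study (E-GEOD-74708)	CCNC	CLTB	COL4A4	CREB1	SCN2B	SOS2	YES1
Metabolism of lipids and lipoproteins	DEGs of the top enriched pathways, ten-astronaut spaceflight study (E-GEOD-74708)	ACSL4	ARSK	CCNC	GM2A	HACL1	PIKFYVE
Axon guidance	DEGs of the top enriched pathways, ten-astronaut spaceflight study (E-GEOD-74708)	CLTB	COL4A4	CREB1	SCN2B	SOS2	YES1
Innate immune system	DEGs of the top enriched pathways, ten-astronaut spaceflight study (E-GEOD-74708)	ATF2	BIRC2	CREB1	NFATC1	PDPK1	YES1
Disease	DEGs of the top enriched pathways, ten-astronaut spaceflight study (E-GEOD-74708)	CCNC	CHMP4C	CREB1	CTNNBIP1	HIF1A	PDPK1
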