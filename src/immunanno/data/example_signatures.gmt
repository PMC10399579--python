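Immune	illustrative example set	PTPRC	CD52	CORO1A	LCP1	LAPTM5
Non_immune	illustrative example set	EPCAM	PECAM1	COL1A1	KRT18	VWF	ALB	CDH1
T	illustrative example set	CD3D	CD3E	CD3G	CD2	TRAC	CD7	LCK
B	illustrative example set	CD79A	CD79B	MS4A1	CD19	TNFRSF13C	BANK1
Monocyte	illustrative example set	LYZ	VCAN	FCN1	CD14	S100A8	S100A9	CSF1R
Macrophage	illustrative example set	CD68	CD163	MRC1	MSR1	C1QA	C1QB	APOE
DC	illustrative example set	FCER1A	CD1C	ITGAX	CLEC4C	LILRA4	FLT3
NK	illustrative example set	GNLY	NKG7	KLRD1	KLRF1	NCR1	NCAM1
ILC	illustrative example set	KIT	IL7R	TNFRSF25	AHR	ICOS	RORC
Mast	illustrative example set	TPSAB1	TPSB2	CPA3	MS4A2	HDC
Neutrophil	illustrative example set	FCGR3B	CSF3R	CEACAM8	ELANE	MPO	S100A12
CD4_T	illustrative example set	CD4	IL7R	CD40LG	TRAC
CD8_T	illustrative example set	CD8A	CD8B	GZMK	TRAC
Naive_B	illustrative example set	TCL1A	IGHD	IL4R	FCER2
Memory_B	illustrative example set	CD27	AIM2	TNFRSF13B	IGHG1
Plasma	illustrative example set	MZB1	XBP1	SDC1	JCHAIN	PRDM1
Classical_monocyte	illustrative example set	CD14	S100A12	VCAN	SELL
Non_classical_monocyte	illustrative example set	FCGR3A	CDKN1C	MS4A7	CX3CR1
M1_macrophage	illustrative example set	NOS2	IL1B	TNF	CXCL9	CXCL10
M2_macrophage	illustrative example set	MRC1	CD163	CCL22	IL10	STAB1
pDC	illustrative example set	CLEC4C	LILRA4	IRF7	TCF4	GZMB
cDC	illustrative example set	CD1C	FCER1A	CLEC10A	ITGAX
NK_bright	illustrative example set	NCAM1	SELL	XCL1	GZMK	KLRC1
NK_dim	illustrative example set	FCGR3A	GZMB	PRF1	SPON2
ILC1	illustrative example set	TBX21	IFNG	IL12RB2	NCR1
ILC2	illustrative example set	GATA3	PTGDR2	IL1RL1	HPGDS
ILC3	illustrative example set	RORC	IL23R	KIT	IL22	AHR
CD4_naive	illustrative example set	CCR7	SELL	TCF7	LEF1	CD4
CD4_central_memory	illustrative example set	CCR7	SELL	CD27	IL7R
CD4_effector_memory	illustrative example set	GZMA	GZMK	CCL5	KLRB1
Treg	illustrative example set	FOXP3	IL2RA	CTLA4	IKZF2
Tfh	illustrative example set	CXCR5	ICOS	PDCD1	BCL6
Th1	illustrative example set	TBX21	IFNG	CXCR3	IL12RB2
Th2	illustrative example set	GATA3	CCR4	IL4	PTGDR2
Th17	illustrative example set	RORC	IL17A	IL17F	CCR6	RORA
CD8_naive	illustrative example set	CCR7	SELL	TCF7	LEF1	CD8B
CD8_central_memory	illustrative example set	CCR7	SELL	CD27	GZMK
CD8_effector_memory	illustrative example set	GZMK	GZMA	CCL5	EOMES
CD8_cytotoxic	illustrative example set	GZMB	PRF1	GNLY	NKG7	KLRG1
CD8_exhausted	illustrative example set	PDCD1	HAVCR2	LAG3	TIGIT	TOX
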