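Activated B cell	tme_cell	CD19	MS4A1	CD79A	CD79B	BLK	CR2	FCRL2	PNOC
Activated CD4 T cell	tme_cell	CD4	IL2RA	CCR4	FOXP3	ICOS	CD28	TNFRSF4	GPR15
Activated CD8 T cell	tme_cell	CD8A	CD8B	GZMA	GZMB	PRF1	IFNG	KLRK1	ZAP70
Activated dendritic cell	tme_cell	CD1A	CD1B	CD1E	CCL13	CCL17	CCL22	LAMP3	CD83
CD56bright natural killer cell	tme_cell	NCAM1	XCL1	XCL2	KLRC1	NCR1	SELL	GZMK	IL7R
CD56dim natural killer cell	tme_cell	KIR2DL1	KIR2DL3	KIR3DL1	FCGR3A	SPON2	GZMH	PRSS23	MYBL1
Natural killer T cell	tme_cell	ZBTB16	KLRB1	SLAMF1	IL18RAP	GATA3	CD3E	CD3D	NKG7
Gamma delta T cell	tme_cell	TRGC1	TRGC2	TRDC	CD3G	KLRD1	CTSW	STMN1	FEZ1
Regulatory T cell	tme_cell	FOXP3	IL2RA	CTLA4	IKZF2	TNFRSF18	LAG3	CCR8	TIGIT
T follicular helper cell	tme_cell	CXCR5	BCL6	PDCD1	IL21	CD200	BTLA	SH2D1A	MAF
Type 1 T helper cell	tme_cell	TBX21	IFNG	STAT4	IL12RB2	CXCR3	CCR5	HAVCR2	IL18R1
Type 2 T helper cell	tme_cell	GATA3	IL4	IL5	IL13	CCR3	IL1RL1	PTGDR2	STAT6
Type 17 T helper cell	tme_cell	RORC	IL17A	IL17F	IL22	CCR6	IL23R	AHR	BATF
Immature B cell	tme_cell	VPREB3	IGLL1	CD38	MME	DNTT	RAG1	RAG2	CD24
Immature dendritic cell	tme_cell	CD1C	FCER1A	CLEC10A	ITGAX	CSF1R	CD209	MRC1	F13A1
MDSC	tme_cell	ITGAM	ARG1	NOS2	S100A8	S100A9	CYBB	IL4R	STAT3
Macrophage	tme_cell	CD68	CD163	MSR1	MRC1	CSF1R	MARCO	VSIG4	C1QA
Mast cell	tme_cell	TPSAB1	TPSB2	CPA3	MS4A2	KIT	CMA1	HDC	GATA2
Monocyte	tme_cell	CD14	FCN1	S100A12	VCAN	LYZ	CSF3R	CD300E	CFP
Neutrophil	tme_cell	FCGR3B	CSF3R	CXCR2	FPR1	SLC25A37	MGAM	CEACAM3	S100A12
Plasmacytoid dendritic cell	tme_cell	CLEC4C	LILRA4	IL3RA	GZMB	IRF7	TCF4	SERPINF1	PTCRA
Eosinophil	tme_cell	CCR3	IL5RA	SIGLEC8	PRG2	EPX	CLC	HRH4	ADORA3
EMT1	stromal_pathway	VIM	ACTA2	COL4A1	ZEB1	ZEB2	TWIST1	SNAI1	SNAI2	CDH2
EMT2	stromal_pathway	FAP	FN1	MMP2	MMP9	POSTN	SPARC	THBS1	COL5A1	COL1A1
EMT3	stromal_pathway	TGFB1	TGFB2	TGFB3	SMAD2	SMAD3	SERPINE1	TNC	LOXL2	ITGB1
Pan-F-TBRS	stromal_pathway	ACTA2	ACTG2	ADAM12	ADAM19	COMP	CNN1	COL4A1	CTGF	CTPS1	FAM101B	FSTL3	HSPB1	IGFBP3	PXDC1	SEMA7A	SH3PXD2A	TAGLN	TGFBI	TNS1	TPM1
Angiogenesis	stromal_pathway	VEGFA	VEGFB	KDR	FLT1	TEK	ANGPT1	ANGPT2	PECAM1	CDH5
Immune checkpoint	immune_panel	PDCD1	CD274	PDCD1LG2	CTLA4	LAG3	HAVCR2	TIGIT	IDO1	BTLA
Antigen presentation	immune_panel	HLA-A	HLA-B	HLA-C	B2M	TAP1	TAP2	HLA-DRA	HLA-DRB1	PSMB9
Cytolytic activity	immune_panel	GZMA	PRF1	GZMB	GZMH	GNLY	NKG7	KLRD1	FASLG	IFNG
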