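B_cells_naive	na	CD19	MS4A1	CD79A	CD79B	TCL1A	IGHD
B_cells_memory	na	CD27	CD19	MS4A1	AIM2	TNFRSF13B
Plasma_cells	na	IGHG1	MZB1	SDC1	CD38	TNFRSF17
T_cells_CD8	na	CD8A	CD8B	GZMK	GZMA	CCL5
T_cells_CD4_naive	na	CD4	CCR7	SELL	TCF7	LEF1
T_cells_CD4_memory_resting	na	CD4	IL7R	CCR7	TNFRSF4
T_cells_CD4_memory_activated	na	CD4	IL2RA	CD69	ICOS	CD40LG
T_cells_follicular_helper	na	CXCR5	BCL6	ICOS	PDCD1	CD200
T_cells_regulatory	na	FOXP3	IL2RA	CTLA4	IKZF2	TNFRSF18
T_cells_gamma_delta	na	TRGC1	TRGC2	TRDC	KLRC1
NK_cells_resting	na	KLRD1	KLRB1	NCR1	KIR2DL3
NK_cells_activated	na	NKG7	GNLY	KLRD1	PRF1	FCGR3A
Monocytes	na	CD14	LYZ	S100A8	S100A9	FCN1
Macrophages_M0	na	CD68	MARCO	FUCA1	MSR1
Macrophages_M1	na	CD80	CD86	NOS2	IL1B	SOCS3
Macrophages_M2	na	CD163	MRC1	MSR1	CCL22	IL10
Dendritic_cells_resting	na	CD1C	FCER1A	CLEC10A	ITGAX
Dendritic_cells_activated	na	CCR7	LAMP3	FSCN1	CD83
Mast_cells_resting	na	TPSAB1	TPSB2	CPA3	MS4A2
Mast_cells_activated	na	KIT	TPSAB1	CMA1	IL13
Eosinophils	na	SIGLEC8	PRG2	EPX	IL5RA	CCR3
Neutrophils	na	FCGR3B	CSF3R	S100A12	CXCR2	FPR1
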