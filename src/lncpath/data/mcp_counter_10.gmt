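T_cells	na	CD3D	CD3E	CD3G	CD5	TRAT1
CD8_T_cells	na	CD8A	CD8B	GZMK
Cytotoxic_lymphocytes	na	GZMA	GZMB	PRF1	KLRD1	NKG7
NK_cells	na	NCR1	KIR2DL3	KLRB1	GNLY
B_lineage	na	CD19	MS4A1	CD79A	CD79B	IGKC
Monocytic_lineage	na	CD14	CD163	CSF1R	ITGAM
Myeloid_dendritic_cells	na	CD1C	FCER1A	CLEC10A
Neutrophils	na	FCGR3B	CSF3R	CXCR2	S100A12
Endothelial_cells	na	PECAM1	VWF	CDH5	CLDN5
Fibroblasts	na	COL1A1	COL3A1	DCN	PDGFRB	FAP
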