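stromal	na	COL1A1	COL1A2	COL3A1	DCN	FAP	PDGFRB	THY1	ACTA2	VIM	FN1
immune	na	PTPRC	CD3D	CD3E	CD8A	CD19	MS4A1	CD14	FCGR3A	NKG7	GZMB
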