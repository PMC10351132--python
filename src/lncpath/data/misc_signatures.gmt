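IFN_gamma	na	IFNG	STAT1	IDO1	CXCL9	CXCL10	CXCL11	HLA-DRA	GZMA	PRF1
CYT	na	GZMA	PRF1
TCR	na	TRAC	TRBC1	TRBC2	CD3D	CD3E	CD3G	ZAP70	LCK
BCR	na	IGHM	IGKC	IGLC1	CD79A	CD79B	BLNK	BTK	SYK
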