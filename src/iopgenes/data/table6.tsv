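snp	gene	histone_modification	enhancer_or_promoter	eqtl_tissues
rs28649910	AFAP1	Yes	Yes	Skin; Whole blood
rs11795066	ANGPTL2	Yes	No	Cerebellum; Esophageal mucosa; Skin; Testis; Tibial nerve; Thyroid; Whole blood
rs368503	ANKH	Yes	No	Esophageal mucosa
rs6546486	ANTXR1	Yes	Yes	None
rs112972174	COL4A1	Yes	Yes	None
rs12123086	COL8A2	Yes	Yes	Whole blood
rs4672075	EFEMP1	Yes	No	Skin; Thyroid
rs7924522	ETS1	Yes	Yes	None
rs722585	GMDS	Yes	No	None
rs74384554	LTBP2	Yes	No	Tibial nerve
rs2433414	ME3	Yes	Yes	Esophageal muscularis; Lung; Skeletal muscle; Skin; Subcutaneous adipose; Tibial nerve; Transformed fibroblasts
rs11606902	PRSS23	Yes	No	Adrenal gland; Esophagus; Skeletal muscle
rs6095946	PTPN1	Yes	Yes	None
rs10774624	SH2B3	Yes	No	Esophageal mucosa; Skin
rs55892100	TES	Yes	Yes	Adrenal gland; Lung; Pancreas; Subcutaneous adipose; Testis; Tibial artery; Tibial nerve; Thyroid; Whole blood
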