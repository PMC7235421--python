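species	tissue	cell_type	gene_symbol	ref_count
human	Blood	T cell	CD3D	8
human	Blood	T cell	CD3E	9
human	Blood	T cell	CD3G	5
human	Blood	T cell	CD2	4
human	Blood	T cell	IL7R	3
human	Blood	T cell	TRAC	2
human	Blood	B cell	CD19	9
human	Blood	B cell	MS4A1	7
human	Blood	B cell	CD79A	6
human	Blood	B cell	CD79B	4
human	Blood	B cell	IGHM	2
human	Blood	Natural killer cell	NKG7	6
human	Blood	Natural killer cell	GNLY	7
human	Blood	Natural killer cell	KLRD1	4
human	Blood	Natural killer cell	NCAM1	5
human	Blood	Natural killer cell	KLRF1	2
human	Blood	Monocyte	CD14	9
human	Blood	Monocyte	LYZ	6
human	Blood	Monocyte	FCN1	3
human	Blood	Monocyte	S100A8	4
human	Blood	Monocyte	VCAN	2
human	Blood	Macrophage	CD68	8
human	Blood	Macrophage	CD163	6
human	Blood	Macrophage	LYZ	3
human	Blood	Macrophage	MRC1	4
human	Blood	Megakaryocyte	PPBP	6
human	Blood	Megakaryocyte	PF4	7
human	Blood	Megakaryocyte	ITGA2B	3
human	Blood	Megakaryocyte	GP9	2
human	Blood	Dendritic cell	FCER1A	5
human	Blood	Dendritic cell	CST3	3
human	Blood	Dendritic cell	CLEC9A	2
human	Lung	Epithelial cell	EPCAM	8
human	Lung	Epithelial cell	KRT18	4
human	Lung	Epithelial cell	KRT19	5
human	Lung	Epithelial cell	SFTPC	3
human	Lung	Endothelial cell	PECAM1	8
human	Lung	Endothelial cell	VWF	6
human	Lung	Endothelial cell	CDH5	4
human	Lung	Endothelial cell	CLDN5	3
human	Connective tissue	Mesenchymal stem cell	COL1A1	5
human	Connective tissue	Mesenchymal stem cell	COL1A2	4
human	Connective tissue	Mesenchymal stem cell	DCN	3
human	Connective tissue	Mesenchymal stem cell	THY1	4
human	Connective tissue	Mesenchymal stem cell	LUM	2
human	Connective tissue	Fibroblast	COL1A1	6
human	Connective tissue	Fibroblast	PDGFRA	4
human	Connective tissue	Fibroblast	FAP	3
human	Connective tissue	Fibroblast	ACTA2	2
mouse	Blood	T cell	CD3D	5
mouse	Blood	T cell	CD3E	6
mouse	Blood	T cell	CD2	2
mouse	Blood	B cell	CD19	6
mouse	Blood	B cell	MS4A1	4
mouse	Blood	B cell	CD79A	3
mouse	Blood	Natural killer cell	NKG7	3
mouse	Blood	Natural killer cell	KLRB1C	2
mouse	Blood	Monocyte	LYZ2	5
mouse	Blood	Monocyte	CD14	4
mouse	Blood	Macrophage	ADGRE1	5
mouse	Blood	Macrophage	CD68	4
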