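rank_sum_order	gene_id	symbol	gene_name	classification
1	ENSG00000210082	MT-RNR2	Mitochondrially encoded 16S rRNA	Mitochondrial
2	ENSG00000203396	RP11-217O12.1	WDR45-like (WDR45L) pseudogene	Pseudogene
3	ENSG00000075624	ACTB	Actin beta	Protein-coding
4	ENSG00000251562	MALAT1	Metastasis associated Lung Adenocarcinoma transcript 1	lncRNA
5	ENSG00000087086	FTL	Ferritin light chain	Protein-coding
6	ENSG00000111640	GAPDH	Glyceraldehyde-3-phosphate Dehydrogenase	Protein-coding
7	ENSG00000236824	BCYRN1	Brain Cytoplasmic RNA 1	scRNA
8	ENSG00000205542	TMSB4X	Thymosin beta 4 X-linked	Protein-coding
9	ENSG00000115414	FN1	Fibronectin 1	Protein-coding
10	ENSG00000026025	VIM	Vimentin	Protein-coding
11	ENSG00000167995	BEST1	Bestrophin 1	Protein-coding
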