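rank	pathway_id	definition	n_genes	genes
1	mmu05200	Pathways in cancer	13	HDAC2,EP300,RAC1,CRK,TGFBR1,CEBPA,NFKB1,SMAD4,CDC42,ITGB1,ELOC,APC,MAP2K1
2	mmu05203	Viral carcinogenesis	9	HDAC2,EP300,RAC1,TBP,NFKB1,CDC42,CDK2,HDAC4,CCND2
3	mmu04810	Regulation of actin cytoskeleton	9	RAC1,CRK,PFN1,CDC42,ACTG1,ITGB1,PPP1CC,APC,MAP2K1
4	mmu04510	Focal adhesion	9	RAC1,CRK,PDPK1,CDC42,ACTG1,ITGB1,CCND2,CAV1,PPP1CC
5	mmu05205	Proteoglycans in cancer	8	RAC1,PDPK1,CDC42,CAMK2A,ACTG1,ITGB1,PPP1CC,MAP2K1
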