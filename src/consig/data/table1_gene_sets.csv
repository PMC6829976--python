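gs_id,n_genes,species,subtype,direction,label
GS125959,2386,human,,,Cisplatin interacting with Homo sapiens associated genes (MeSH:D002945) in CTD
GS257116,883,mouse,,,Cisplatin interacting with Mus musculus associated genes (MeSH:D002945) in CTD
GS263765,616,rat,,,Cisplatin interacting with Rattus norvegicus associated genes (MeSH:D002945) in CTD
GS357326,378,human,,,Genes from CTD that interact with cisplatin and are conserved in human and mouse
GS357330,219,human,,,Genes from CTD that interact with cisplatin and are conserved in human and rat
GS357329,150,human,,,Genes from CTD that interact with cisplatin and are conserved in rat and mouse
GS271882,96,human,,,Genes from CTD that interact with cisplatin and are conserved in human mouse and rat
GS237976,319,human,,,MeSH Cisplatin:D002945
GS271616,215,human,BL1,up,Genes upregulated in the BL1 subtype of triple negative breast cancer
GS271617,154,human,BL2,up,Genes upregulated in the BL2 subtype of triple negative breast cancer
GS271618,535,human,IM,up,Genes upregulated in the IM subtype of triple negative breast cancer
GS271619,247,human,M,up,Genes upregulated in the M subtype of triple negative breast cancer
GS271621,805,human,LAR,up,Genes upregulated in LAR subtype of triple negative breast cancer
GS271724,829,human,MSL,up,Genes upregulated in the MSL subtype of triple negative breast cancer
GS271627,251,human,BL1,down,Genes downregulated in the BL1 subtype of triple negative breast cancer
GS271636,127,human,BL2,down,Genes downregulated in the BL2 subtype of triple negative breast cancer
GS271640,302,human,IM,down,Genes downregulated in the IM subtype of triple negative breast cancer
GS271722,446,human,M,down,Genes downregulated in the M subtype of triple negative breast cancer
GS271729,382,human,LAR,down,Genes downregulated in the LAR subtype of triple negative breast cancer
GS271725,255,human,MSL,down,Genes downregulated in the MSL subtype of triple negative breast cancer
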