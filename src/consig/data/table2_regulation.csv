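# The 20 conserved cisplatin-associated genes differentially expressed in the
# four tumour-cell-only TNBC subtypes, with per-subtype regulation status and
# a cell-death annotation flag.
#
# Column placement for the sensitive-subtype statuses of ADM, CAV1, HSPB1,
# PTK2, MSH2, GJA1, BCL2 and FOS is fixed by constraint satisfaction against
# the published per-subtype counts (BL1 2 up / 5 down, BL2 4 up / 0 down,
# M 5 up / 3 down, LAR 8 up / 3 down), the 16 up-in-any / 11 down-in-any
# totals, the 13-gene resistant signature with its 7 (LAR-only) / 3 (M-only) /
# 3 (both) exclusivity split, and the 15-of-20 cell-death flags.  The split of
# the five sensitive-subtype UP genes between BL1 (ADM, CAV1) and BL2 (HSPB1,
# MSH2, PTK2) is the one residual degree of freedom; it does not affect any
# derived count.
gene,name,BL1,BL2,M,LAR,death
ABCC2,ATP binding cassette subfamily C member 2,NONE,NONE,NONE,UP,0
ADM,adrenomedullin,UP,NONE,UP,NONE,1
AKT1,AKT serine/threonine kinase 1,NONE,NONE,NONE,UP,1
BCL2,BCL2 apoptosis regulator,DOWN,NONE,NONE,NONE,1
BCL2L1,BCL2 like 1,NONE,NONE,NONE,UP,1
CASP8,caspase 8,NONE,NONE,DOWN,UP,1
CAV1,caveolin 1,UP,NONE,NONE,NONE,1
CLU,clusterin,DOWN,NONE,NONE,UP,1
FAS,Fas cell surface death receptor,NONE,NONE,DOWN,NONE,1
FOS,Fos proto-oncogene AP-1 transcription factor subunit,DOWN,NONE,NONE,NONE,1
GSR,glutathione-disulfide reductase,NONE,NONE,NONE,UP,0
GJA1,gap junction protein alpha 1,DOWN,UP,UP,NONE,1
HSPB1,heat shock protein family B (small) member 1,NONE,UP,NONE,UP,1
MSH2,mutS homolog 2,NONE,UP,NONE,DOWN,1
NOX4,NADPH oxidase 4,DOWN,NONE,UP,NONE,1
NQO1,NAD(P)H quinone dehydrogenase 1,NONE,NONE,NONE,UP,1
PTK2,protein tyrosine kinase 2,NONE,UP,NONE,NONE,1
TUBA1A,tubulin alpha 1a,NONE,NONE,UP,DOWN,0
VCAM1,vascular cell adhesion molecule 1,NONE,NONE,DOWN,NONE,0
VIM,vimentin,NONE,NONE,UP,DOWN,0
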