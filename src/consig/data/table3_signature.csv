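# The 13-gene cisplatin-resistance signature: genes whose regulation in a
# resistant subtype (LAR or M) differs from their status in every sensitive
# subtype (BL1, BL2).  One row per contributing (gene, resistant subtype).
gene,subtype,direction
ABCC2,LAR,UP
AKT1,LAR,UP
BCL2L1,LAR,UP
CASP8,LAR,UP
CASP8,M,DOWN
CLU,LAR,UP
FAS,M,DOWN
GSR,LAR,UP
MSH2,LAR,DOWN
NOX4,M,UP
NQO1,LAR,UP
TUBA1A,M,UP
TUBA1A,LAR,DOWN
VCAM1,M,DOWN
VIM,M,UP
VIM,LAR,DOWN
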