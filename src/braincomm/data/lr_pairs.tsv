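ligand	receptor
SEMA4A	NRP1
BMP7	BMPR1A+ACVR2A
BMP7	BMPR1B+ACVR2A
BMP7	BMPR1B+BMPR2
WNT5A	ROR1
SPP1	ITGAV
C3	CD46
PDGFA	PDGFRA
MLLT4	EPHB6
GAS6	MERTK
INHBB	ACVR1C+ACVR2A
FIGF	NRP2
SEMA3A	NRP1+PLXNA1
SEMA3C	NRP1
CNTN2	NRP1
TIMP3	ADAM17
CD36	TLR4
RELN	ITGB1
NRG2	ERBB3
SPTAN1	PTPRA
CYR61	ITGAV
COL7A1	ITGB1
EFNA3	EPHA6
SST	SSTR2
RSPO3	FZD8
MLLT4	PVRL3
FGF1	FGFR2
TGFB1	TGFBR1+TGFBR2
IL6	IL6R+IL6ST
TNF	TNFRSF1A
VEGFA	FLT1
BDNF	NTRK2
NGF	NTRK1
EFNA1	EPHA4
DLL1	NOTCH1
JAG1	NOTCH1
CX3CL1	CX3CR1
CSF1	CSF1R
APOE	LRP1
APP	CD74
PSAP	GPR37L1
IGF1	IGF1R
EGF	EGFR
HGF	MET
CXCL12	CXCR4
CCL2	CCR2
ICAM1	ITGAL+ITGB2
LAMB1	ITGB1
NCAM1	FGFR1
PTN	PTPRZ1
MDK	SDC1
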