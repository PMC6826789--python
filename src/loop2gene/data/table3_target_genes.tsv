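locus	target_genes	nearest_genes
1p34.3	GNL2,C1orf122	GNL2,RSPO1
2p16.1	BCL11A	BCL11A
8q24.1	MIR1207,PVT1,LINC00824	LINC00824
9p21.3	CDKN2A,CDKN2B,CDKN2B-AS1,MIR31HG	CDKN2B-AS1
11p13	WT1,WT1-AS,CD59,PAX6,RCN1	WT1-AS
12p12.1	BHLHE41,PTHLH,SSPN,LRMP	SSPN
12q24.11	SH2B3,PHETA1,ACAD10,ARPC3,BRAP,IFT81,LINC02356	SH2B3,ATXN2
12q24.21	TBX3	TBX3
15q15.1	SRP14,SRP14-AS1,BMF,BAHD1,CCDC9B,GPR176,KNSTRN,PAK6,PLCB2,PLCB2-AS1,THBS1,EIF2AK4,CHST14,DISP2,FSIP1,INAFM2,PLA2G4B,RASGRP1,SPINT1,ANKRD63,PHGR1,SPINT1-AS1,C15orf56	SRP14,SRP14-AS1,EIF2AK4
15q21.2	DMXL2,TRPM7,TNFAIP8L3	CYP19A1
17q11.2	RAB11FIP4,MIR193A,TEFM,RNU6ATAC7P	RAB11FIP4,NF1,EVI2A,EVI2B
17q12	HNF1B,DUSP14,MRM1,MRPL45,SRCIN1,TBC1D3,C17orf78	HNF1B
17q21.32	SNX11,MIR1203,SKAP1-AS1,SKAP1,CBX1,HOXB1,HOXB2,HOXB3,HOXB4,HOXB5,HOXB6,HOXB7,HOXB8,HOXB9,HOXB13,HOXB-AS1,HOXB-AS3,HOXB-AS4,PRR15L,CDK5RAP3,LRRC46,MRPL10,NFE2L1,SCRN2,CALCOCO2,COPZ2,DLX3,KPNB1,PNPO,SNF8,SP2,SP2-AS1,SP6,MIR10A,MIR152,MIR196A1,MIR3185,PHOSPHO1	SNX11,MIR1203,SKAP1-AS1,SKAP1,CBX1
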