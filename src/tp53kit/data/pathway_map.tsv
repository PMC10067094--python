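pathway	gene
RTK	EGFR
RTK	ERBB2
RTK	ALK
RTK	ROS1
RTK	MET
RTK	RET
RTK	FGFR1
RTK	FGFR2
RTK	FGFR3
RTK	KIT
RTK	PDGFRA
RTK	NTRK1
cell_cycle	CDKN2A
cell_cycle	CDKN2B
cell_cycle	RB1
cell_cycle	CCND1
cell_cycle	CCNE1
cell_cycle	CDK4
cell_cycle	CDK6
DDR	ATM
DDR	ATR
DDR	BRCA1
DDR	BRCA2
DDR	CHEK1
DDR	CHEK2
DDR	MLH1
DDR	MSH2
DDR	MSH6
DDR	PMS2
DDR	POLE
DDR	PALB2
DDR	RAD51
DDR	FANCA
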