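M9.2	A37	ALAS2	BCL2L1	BPGM	C14ORF45	C1ORF128	CA1	EPB42	FAM46C	FECH	GMPR	GPR146	GYPB	GYPE	IFIT1L	KRT1	MARCH8	NFIX	OR2W3	OSBP2	PLEK2	SELENBP1	SLC14A1	SLC4A1	SNCA	TMCC2	TMOD1	TNS1	TRIM10	TUBB2A	XK
M11.2	A37	ABCC4	AMFR	BAT3	BMP2K	C17ORF39	C9ORF40	DNAJB2	EIF1B	GDE1	GNA12	HS.211743	HS.57079	IQWD1	JAZF1	MED25	NSUN3	ODC1	POLR1D	PPP2R5B	PSME4	RANBP10	RNF14	RSRC1	SELK	SLC2A1	SNX3	TBC1D22B	TMEM183A	TMEM183B	UBE2F	UBQLN1	WBP2	WDR26	WDR45	WDR51B	WNK1	ZBTB44	ZER1	ZNF653
M11.3	A37	ASCC2	C18ORF10	C18ORF10	DPM2	EPB49	FBXO7	FBXO7	GATA1	HAGH	HEMGN	HEMGN	HMBS	KEL	LOC284422	LOC440359	LOC441081	MBNL3	MBNL3	MYL4	PDZK1IP1	PHOSPHO1	RUNDC3A	SESN3	TESC	TGM2	TRIM10	TSPAN5	VWCE
M11.4	A37	AP2M1	AP2M1	AP2S1	ATG9A	ATG9A	B4GALT3	BCL2L13	C13ORF15	C19ORF62	CYB5R3	DAP	DENND1A	FAM134A	HK1	JUND	MSI2	NTAN1	NUCB1	PA2G4	POLR1D	TCEB2	UBAC1	UBAP1	UBL7	UROD	WDR13	WIPI2	ZMAT2
M12.11	A37	ALDH5A1	BNIP3L	BNIP3L	C20ORF108	DNAJA4	FAM104A	HBD	HS.105618	HS.291319	ISCA1L	LOC389293	MPP1	MXI1	PRDX2	PRDX2	RAB2B	RAD23A	RIOK3	RPIA	SIAH2	SLC1A5	TFDP1	TFDP1	TRAK2	TSTA3	UBE2O	YOD1
M13.26	A37	AP2A1	ATP6V0C	BMP2K	C16ORF35	C19ORF22	C2ORF24	C9ORF78	CCDC23	CREG1	EIF2AK1	ELOF1	FAM100A	FOXO4	FURIN	GABARAPL2	GCLC	GPX1	H1F0	HDGF	ISCA1	ISCA1	LYL1	MAF1	MKRN1	NINJ2	NP	PIM1	PINK1	PNPLA2	PRR6	PSMF1	RFESD	RNF123	RNF14	STK33	STOM	SYT15	TERF2IP	TFDP2	XPO7	YPEL3
M13.30	A37	ABCC13	ADIPOR1	ARL4A	BLVRB	BOAT	C16ORF35	CARM1	CES3	CSDA	FBXO9	FIS1	FKBP8	FLJ20489	GLUL	GSPT1	GUK1	GYPC	HAGH	HBM	HBQ1	HPS1	HPS1	PBX1	PTMS	SHARPIN	SLC25A39	ST6GALNAC4	ST6GALNAC4	TMEM86B	UBL7	UBXD1
M14.53	A37	BCL2L1	BSG	CDC34	CHPT1	CHPT1	FHL2	GLRX5	IGF2BP2	KLF1	LOC650832	LOC653778	LOC654103	MAP2K3	MARCH8	RBM38	RIOK3	TMEM63B
M15.53	A37	BRD4	C16ORF35	CDKL1	DPM2	EPB41	HMBS	HPS1	IQWD1	KLC3	LOC643008	LOC648434	LOC650898	MAP2K3	MICAL2	MICALCL	MXI1	RAB3IL1	RP11-529I10.4	SLC38A5	SLC6A8	TCP11L2	TGM2	TMPRSS9	TTC25	WNK1
M15.74	A37	ANKRD9	ATP6V0C	C22ORF25	C5ORF4	E2F2	FHL2	HMG2L1	LGALS3	LOC653907	MAP2K3	MARCH2	MCOLN1	MGC13057	PPM1A	PPM1A	RNF10	RNF11	SLC6A10P	SMOX	SRRD	TMEM158	UBE2H
M15.100	A37	ARHGEF12	C14ORF45	CISD2	CMBL	FLCN	GCAT	GYPE	HBBP1	LOC253012	PCSK1N	PLVAP	RHD	SLC6A9	SPTB	TBCEL	TMEM56	YPEL4
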