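clinical_area	gene	inheritance	lt_0_005	f_0_005_to_0_01	f_0_01_to_0_05	f_0_05_to_0_1	ge_0_1
hereditary_cancer	APC	Dominant	6	0	0	0	0
hereditary_cancer	ATM	Recessive	104	1	0	0	0
hereditary_cancer	BARD1	Dominant	22	0	0	0	0
hereditary_cancer	BLM	Recessive	38	2	1	0	0
hereditary_cancer	BMPR1A	Dominant	3	1	0	0	0
hereditary_cancer	BRCA1	Dominant	67	0	2	0	0
hereditary_cancer	BRCA2	Dominant	103	2	1	0	0
hereditary_cancer	BRIP1	Recessive	32	0	1	0	0
hereditary_cancer	CDH1	Dominant	5	0	0	0	0
hereditary_cancer	CDKN2A	Dominant	4	0	0	0	0
hereditary_cancer	CHEK2	Dominant	29	3	2	0	1
hereditary_cancer	CTRC	Dominant	11	1	0	0	0
hereditary_cancer	EPCAM	Recessive	9	1	0	0	0
hereditary_cancer	FANCC	Recessive	23	1	0	0	0
hereditary_cancer	MEN1	Dominant	0	0	0	0	0
hereditary_cancer	MLH1	Dominant	5	0	0	0	0
hereditary_cancer	MRE11A	Recessive	18	1	0	0	0
hereditary_cancer	MSH2	Dominant	7	1	0	0	0
hereditary_cancer	MSH6	Dominant	25	0	1	0	0
hereditary_cancer	MUTYH	Recessive	19	3	2	0	1
hereditary_cancer	NBN	Recessive	33	1	1	0	0
hereditary_cancer	NF1	Dominant	23	1	0	0	0
hereditary_cancer	PALB2	Dominant	35	2	1	0	0
hereditary_cancer	PMS2	Dominant	32	0	0	0	0
hereditary_cancer	PTCH1	Dominant	2	0	0	0	0
hereditary_cancer	PTEN	Dominant	2	0	0	0	0
hereditary_cancer	RAD50	Recessive	42	2	3	0	0
hereditary_cancer	RAD51C	Recessive	19	3	0	0	0
hereditary_cancer	SMAD4	Dominant	2	0	0	0	0
hereditary_cancer	SPINK1	Dominant	1	0	1	0	0
hereditary_cancer	STK11	Dominant	0	0	0	0	0
hereditary_cancer	TP53	Dominant	1	0	0	0	0
hereditary_cancer	VHL	Dominant	0	0	0	0	0
primary_ciliary_dyskinesia	ARMC4	Recessive	36	3	0	0	0
primary_ciliary_dyskinesia	C21orf59	Recessive	7	1	1	0	0
primary_ciliary_dyskinesia	CCDC103	Recessive	3	0	0	0	0
primary_ciliary_dyskinesia	CCDC114	Recessive	6	0	0	0	0
primary_ciliary_dyskinesia	CCDC151	Recessive	16	1	0	0	0
primary_ciliary_dyskinesia	CCDC39	Recessive	22	2	0	0	0
primary_ciliary_dyskinesia	CCDC40	Recessive	32	1	1	0	0
primary_ciliary_dyskinesia	CCDC65	Recessive	17	0	1	0	0
primary_ciliary_dyskinesia	CCNO	Recessive	0	0	0	0	0
primary_ciliary_dyskinesia	DNAAF1	Recessive	19	2	1	0	0
primary_ciliary_dyskinesia	DNAAF2	Recessive	12	0	0	0	0
primary_ciliary_dyskinesia	DNAAF3	Recessive	16	2	1	0	0
primary_ciliary_dyskinesia	DNAH11	Recessive	80	1	2	0	0
primary_ciliary_dyskinesia	DNAH5	Recessive	113	0	2	0	0
primary_ciliary_dyskinesia	DNAI1	Recessive	15	0	1	0	0
primary_ciliary_dyskinesia	DNAI2	Recessive	21	1	1	0	0
primary_ciliary_dyskinesia	DNAL1	Recessive	3	0	0	0	0
primary_ciliary_dyskinesia	DRC1	Recessive	22	0	2	0	0
primary_ciliary_dyskinesia	DYX1C1	Recessive	18	1	0	0	0
primary_ciliary_dyskinesia	RPGR	Recessive	1	0	0	0	0
primary_ciliary_dyskinesia	RSPH1	Recessive	9	1	2	0	0
primary_ciliary_dyskinesia	RSPH4A	Recessive	27	1	0	0	0
primary_ciliary_dyskinesia	RSPH9	Recessive	4	0	0	0	0
primary_ciliary_dyskinesia	SPAG1	Recessive	21	2	0	0	0
primary_ciliary_dyskinesia	ZMYND10	Recessive	16	0	0	0	0
arrhythmia_cardiomyopathy	BAG3	Dominant	2	0	0	0	0
arrhythmia_cardiomyopathy	CACNA1C	Dominant	6	0	0	0	0
arrhythmia_cardiomyopathy	CASQ2	Recessive	15	0	0	0	0
arrhythmia_cardiomyopathy	DES	Recessive	5	0	0	0	0
arrhythmia_cardiomyopathy	DSC2	Dominant	13	0	0	0	0
arrhythmia_cardiomyopathy	DSG2	Dominant	19	0	0	0	0
arrhythmia_cardiomyopathy	DSP	Recessive	21	0	0	0	0
arrhythmia_cardiomyopathy	FHL1	Dominant	0	0	0	0	0
arrhythmia_cardiomyopathy	HCN4	Dominant	5	0	0	0	0
arrhythmia_cardiomyopathy	JUP	Recessive	7	0	0	0	0
arrhythmia_cardiomyopathy	KCNE1	Dominant	0	0	0	0	0
arrhythmia_cardiomyopathy	KCNH2	Dominant	5	0	2	0	0
arrhythmia_cardiomyopathy	KCNQ1	Dominant	15	0	1	0	0
arrhythmia_cardiomyopathy	LAMP2	Dominant	0	0	0	0	0
arrhythmia_cardiomyopathy	LMNA	Dominant	1	0	0	0	0
arrhythmia_cardiomyopathy	MYBPC3	Dominant	17	0	0	0	0
arrhythmia_cardiomyopathy	NKX2-5	Dominant	1	0	0	0	0
arrhythmia_cardiomyopathy	PKP2	Dominant	18	0	1	0	0
arrhythmia_cardiomyopathy	PLN	Dominant	0	0	0	0	0
arrhythmia_cardiomyopathy	SCN5A	Dominant	9	0	0	0	0
arrhythmia_cardiomyopathy	TRDN	Recessive	6	1	2	0	0
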