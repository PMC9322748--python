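probeset_id	gene_description	gene_symbol	M_contrast3	M_contrast2
Cfa.11069.1.A1_s_at	Splicing factor 3a subunit 1	SF3A1	0.39123732	-0.689723
Cfa.12226.1.A1_at	Double-headed protease inhibitor, submandibular gland	LOC111092171	0.13751692	-0.3472223
Cfa.6267.3.S1_s_at	Cysteine rich protein 1	CRIP1	0.43971334	-0.3231234
Cfa.758.1.S1_at	Annexin A1	ANXA1	0.57352154	-0.2534974
Cfa.1341.1.S1_s_at	Integral membrane protein 2B	ITM2B	0.09784959	-0.2300856
Cfa.11085.1.A1_at	Regulator of G-protein signaling 2	RGS2	0.40545754	-0.2130524
Cfa.3290.1.S1_at	Kruppel-like factor 6	KLF6	0.50830344	-0.2017464
CfaAffx.22128.1.S1_at	S100 calcium binding protein P	S100P	0.17803743	-0.1172426
Cfa.5123.1.A1_at	Eukaryotic translation initiation factor 3, subunit F	EIF3F	0.20471796	-0.1131341
Cfa.14421.1.S1_at	Guanine nucleotide binding protein (G protein), gamma 5	GNG5	0.22490961	-0.1044874
Cfa.415.1.S1_at	Catenin (cadherin-associated protein), beta 1	CTNNB1	0.09870051	-0.0672268
CfaAffx.5204.1.S1_s_at	Cytochrome c, somatic	CYCS	-0.3244678	0.117936
CfaAffx.17908.1.S1_s_at	Mitochondrial import receptor subunit TOM20 homolog	TOMM20	-0.6786731	0.18335565
Cfa.9946.1.S1_at	General transcription factor IIA, 2	GTF2A2	-0.4167318	0.19831684
CfaAffx.727.1.S1_x_at	FAM168A, family with sequence similarity 168, member A	FAM168A	-0.4299426	0.20356136
CfaAffx.16356.1.S1_s_at	LOC608756, similar to 60 kDa heat shock protein, mitochondrial precursor	HSPD1	-0.5398836	0.21506239
Cfa.1128.1.S1_at	KPNA2, karyopherin alpha 2 (RAG cohort 1, importin alpha 1)	KPNA2	-0.2790694	0.24160302
Cfa.6212.1.A1_at	Mitochondrial 28S ribosomal protein S21	MRPS21	-0.5480801	0.40259764
Cfa.12820.2.A1_a_at	Cysteine-rich, angiogenic inducer, 61	CYR61	-0.574112	0.60011614
CfaAffx.386.1.S1_x_at	40S Ribosomal protein S20	RPS20	-0.7323368	0.70095917
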