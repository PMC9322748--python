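probeset_id	gene_description	gene_symbol	M_contrast3	M_contrast2
CfaAffx.16440.1.S1_at	2'-5'-Oligoadenylate synthase-like protein	OASL	0.851	0.770
CfaAffx.2163.1.S1_at	Antigen peptide transporter 2	TAP2	0.649	0.619
CfaAffx.16198.1.S1_s_at	Trefoil factor 1	TFF1	0.924	0.599
Cfa.12501.1.A1_at/CfaAffx.19068.1.S1_at/CfaAffx.19068.1.S1_s_at	Insulin-like growth factor-binding protein 1	IGFBP1	0.453	0.397
CfaAffx.29762.1.S1_at	NADPH oxidase organizer 1	NOXO1	0.556	0.417
CfaAffx.15121.1.S1_at	Interferon-induced protein with tetratricopeptide repeats 1	IFIT1	0.855	0.407
CfaAffx.21951.1.S1_s_at	Eukaryotic translation elongation factor 1 alpha 1	EEF1A1	0.285	0.332
Cfa.21191.2.S1_a_at	2'-5'-Oligoadenylate synthase 1	OAS1	1.028	0.284
Cfa.10757.1.S1_at	Ubiquitin-like protein ISG15	ISG15	0.953	0.284
Cfa.2878.1.A1_s_at	Ceruloplasmin	CP	0.965	0.271
CfaAffx.14226.1.S1_s_at	DExD/H-box helicase 60	DDX60	0.515	0.267
CfaAffx.17868.1.S1_at	Glutathione peroxidase 1	GPX1	0.343	0.213
CfaAffx.18742.1.S1_at	Eukaryotic translation initiation factor 3 subunit A	EIF3A	0.306	0.185
Cfa.20996.1.S1_at	MHC class I DLA-12	DLA-12	0.348	0.118
Cfa.15976.1.S1_at	ATP synthase F1 subunit epsilon	ATP5F1E	-0.282	-0.085
CfaAffx.23922.1.S1_x_at	40S ribosomal protein S24	RPS24	-0.641	-0.155
Cfa.5563.1.A1_s_at	Protein disulfide isomerase family A member 6	PDIA6	-0.332	-0.180
Cfa.3039.1.A1_at	ATPase Na+/K+ transporting subunit alpha 1	ATP1A1	-0.158	-0.189
Cfa.9039.1.A1_at	Fos proto-oncogene, AP-1 transcription factor subunit	FOS	-0.427	-0.190
Cfa.1408.1.S1_at	Reticulon 4	RTN4	-0.226	-0.303
Cfa.12512.1.A1_at	Ecm29 proteasome adaptor and scaffold	ECPAS	-0.196	-0.387
Cfa.31.1.S1_s_at	Acidic nuclear phosphoprotein 32 family member A	ANP32A	-0.428	-0.396
Cfa.15462.1.A1_at	Metallothionein-1	LOC100686073	-0.522	-0.489
Cfa.7907.2.A1_a_at	Uncharacterized LOC611209	LOC611209	-0.530	-0.645
CfaAffx.11648.1.S1_at	Chromodomain helicase DNA binding protein 7	CHD7	-0.870	-0.834
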