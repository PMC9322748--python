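probeset_id	gene_description	gene_symbol	M_contrast3	M_contrast2	M_contrast1
CfaAffx.14226.1.S1_s_at	DEAD (Asp-Glu-Ala-Asp) box polypeptide 60	DDX60	0.515	0.267	0.499
CfaAffx.18742.1.S1_at	Eukaryotic translation initiation factor 3 subunit A	EIF3A	0.306	0.185	0.215
Cfa.15462.1.A1_at	Metallothionein-1	LOC100686073	-0.522	-0.489	-0.556
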