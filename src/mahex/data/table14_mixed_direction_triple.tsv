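probeset_id	gene_description	gene_symbol	M_contrast1	M_contrast3	M_contrast2
Cfa.6267.3.S1_s_at	Cysteine rich protein 1 (CRIP1)	CRIP1	-0.238149286	0.43971334	-0.3231234
Cfa.758.1.S1_at	Annexin A1	ANXA1	0.309584226	0.57352154	-0.2534974
Cfa.11085.1.A1_at	Regulator of G-protein signaling 2	RGS2	-0.302506821	0.40545754	-0.2130524
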