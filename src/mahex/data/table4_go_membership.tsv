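subtree	category	gene
biological_process	cellular metabolic process and regulation, organic substance / nitrogen compound metabolic process	CENPF
biological_process	cellular metabolic process and regulation, organic substance / nitrogen compound metabolic process	GEN1
biological_process	cellular metabolic process and regulation, organic substance / nitrogen compound metabolic process	STYK1
biological_process	cellular metabolic process and regulation, organic substance / nitrogen compound metabolic process	KHDRBS3
biological_process	cellular metabolic process and regulation, organic substance / nitrogen compound metabolic process	ATP13A2
biological_process	regulation of metabolic process	CENPF
biological_process	regulation of metabolic process	KHDRBS3
biological_process	regulation of metabolic process	ATP13A2
biological_process	establishment of localization	CENPF
biological_process	establishment of localization	ATP13A2
biological_process	establishment of localization	SLC7A1
biological_process	macromolecule localization, cellular localization	CENPF
biological_process	macromolecule localization, cellular localization	ATP13A2
biological_process	regulation of molecular function, cellular homeostasis, regulation of biological quality	KRIT1
biological_process	regulation of molecular function, cellular homeostasis, regulation of biological quality	ATP13A2
biological_process	biosynthetic process, cell cycle process, negative regulation of cellular process, chromosome segregation	CENPF
biological_process	biosynthetic process, cell cycle process, negative regulation of cellular process, chromosome segregation	GEN1
biological_process	positive regulation of cellular process, cellular response to stimulus, cellular component organization or biogenesis, response to stress	GEN1
biological_process	positive regulation of cellular process, cellular response to stimulus, cellular component organization or biogenesis, response to stress	ATP13A2
biological_process	anatomical structure development, regulation of developmental process, multicellular organism development	CENPF
biological_process	anatomical structure development, regulation of developmental process, multicellular organism development	KRIT1
biological_process	transmembrane transport	ATP13A2
biological_process	transmembrane transport	SLC7A1
biological_process	positive regulation of transport, export from cell, response to chemical, regulation of localization, catabolic process	ATP13A2
biological_process	negative regulation of metabolic process	CENPF
biological_process	cell cycle checkpoint, microtubule-based process	GEN1
biological_process	anatomical structure formation involved in morphogenesis, establishment or maintenance of cell polarity	KRIT1
biological_process	oxidation-reduction process	LOC610994
molecular_function	identical protein binding	CENPF
molecular_function	identical protein binding	GEN1
molecular_function	identical protein binding	KHDRBS3
molecular_function	nucleic acid binding	Gpatch4
molecular_function	nucleic acid binding	GEN1
molecular_function	nucleic acid binding	KHDRBS3
molecular_function	nucleoside phosphate binding, anion binding, ribonucleotide binding	STYK1
molecular_function	nucleoside phosphate binding, anion binding, ribonucleotide binding	ATP13A2
molecular_function	protein dimerization activity	CENPF
molecular_function	protein dimerization activity	GEN1
molecular_function	cation binding	GEN1
molecular_function	cation binding	ATP13A2
molecular_function	nucleotide binding	STYK1
molecular_function	nucleotide binding	ATP13A2
molecular_function	inorganic molecular entity transmembrane transporter activity	SLC7A1
molecular_function	protein kinase activity, transferase activity, transferring phosphorus-containing groups	STYK1
molecular_function	transcription factor binding, protein C-terminus binding, dynein complex binding, cytoskeletal protein binding	CENPF
molecular_function	phospholipid binding, hydrolase activity, acting on acid anhydrides	ATP13A2
molecular_function	hydrolase activity, acting on ester bonds, deoxyribonuclease activity	GEN1
molecular_function	protein domain specific binding	KHDRBS3
molecular_function	ion transmembrane transporter activity	SLC7A1
cellular_component	intracellular organelle	CENPF
cellular_component	intracellular organelle	GEN1
cellular_component	intracellular organelle	KRIT1
cellular_component	intracellular organelle	KHDRBS3
cellular_component	intracellular organelle	ATP13A2
cellular_component	intracellular non-membrane-bounded organelle	CENPF
cellular_component	intracellular non-membrane-bounded organelle	GEN1
cellular_component	intracellular non-membrane-bounded organelle	KRIT1
cellular_component	membrane-bounded organelle	CENPF
cellular_component	membrane-bounded organelle	KHDRBS3
cellular_component	membrane-bounded organelle	ATP13A2
cellular_component	integral component of membrane	STYK1
cellular_component	integral component of membrane	ATP13A2
cellular_component	integral component of membrane	SLC7A1
cellular_component	non-membrane-bounded organelle	CENPF
cellular_component	non-membrane-bounded organelle	GEN1
cellular_component	non-membrane-bounded organelle	KRIT1
cellular_component	intracellular organelle lumen	CENPF
cellular_component	intracellular organelle lumen	KHDRBS3
cellular_component	centrosome	CENPF
cellular_component	centrosome	GEN1
cellular_component	plasma membrane bounded cell projection	CENPF
cellular_component	plasma membrane bounded cell projection	ATP13A2
cellular_component	organelle lumen	CENPF
cellular_component	organelle lumen	KHDRBS3
cellular_component	plasma membrane	STYK1
cellular_component	plasma membrane	SLC7A1
cellular_component	intrinsic component of organelle membrane, endosome, organelle membrane, intracellular vesicle	ATP13A2
cellular_component	cilium, ciliary basal body, organelle envelope, kinetochore, chromosome, centromeric region	CENPF
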