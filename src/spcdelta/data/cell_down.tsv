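category	gene	description	rsc
Cytoskeletal	TUBB2A	Tubulin beta-2A chain	-42.9
Cytoskeletal	ACTC1	Alpha-cardiac actin	-1.7
Cytoskeletal	ACTB	Beta-actin	-1.5
Cytoskeletal	PLEC	Plectin	-1.2
Epithelial-Mesenchymal Transition	YWHAE	14-3-3ε	-10.0
Epithelial-Mesenchymal Transition	PPP2CA	Serine/threonine-protein phosphatase 2A catlytic subunit alpha isolform	-3.3
Epithelial-Mesenchymal Transition	VIM	Vimentin	-1.2
Cellular metabolism	ECHS1	Enoyl-CoA Hydratase 1	-3.7
Cellular metabolism	SLC25A3	Solute carrier damily 25 member 3	-2.4
Cellular metabolism	CS	Citrate synthase	-2.4
Cellular migration/motility	EFHD2	Swiprosin-1	-4.1
Cellular migration/motility	PFN1	Profilin-1	-1.8
Drug resistance	GLO1	Glyoxalase 1	-3.1
Drug resistance	TAGLN2	Transgelin-2	-3.0
Protein transport	SEC63	Translocation protein SEC63 homolog	-3.4
Cell adhesion	RSU1	Ras suppressor protein 1	-2.8
Immune response	WARS	Tryptophan-tRNA ligase,	-2.8
Prognosticator of survival	ALB	Serum albumin	-1.8
Post-translational modifications	HIST1H4B	Histone H4	-1.6
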