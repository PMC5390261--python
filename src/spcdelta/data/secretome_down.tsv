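category	gene	description	rsc
Cytoskeletal	TUBB2A	Tubulin beta-2A chain (Tubulin beta class IIa)	-8.0
Cytoskeletal	APLP2	Amyloid-like protein 2	-5.8
Cytoskeletal	RDX	Radixin	-5.6
Cytoskeletal	FLNB	Filamin-B	-5.0
Cytoskeletal	FLNA	Filamin-A	-4.5
Cytoskeletal	ACTN2	Alpha-actinin-2	-4.5
Cellular growth/survival	UBA1	Ubiquitin-like modifier-activating enzyme 1	-5.6
Cellular growth/survival	EIF4A2	Eukaryotic initiation factor 4A-II	-4.7
Cellular growth/survival	XPO1	Exportin-1	-3.6
Cellular growth/survival	CTSD	Cathepsin D (EC 3.4.23.5)	-3.4
Cellular growth/survival	CLTC	Clathrin heavy chain 1	-2.2
Extracellular matrix	FN1	FN1 protein (Fibronectin 1)	-15.3
Extracellular matrix	LAMC2	Laminin subunit gamma-2	-10.2
Extracellular matrix	LAMB3	Laminin subunit beta-3	-7.8
Extracellular matrix	APP A4	Amyloid beta A4 protein	-3.2
Drug resistance	FASN	Fatty acid synthase (EC 2.3.1.85)	-5.3
Drug resistance	TAGLN2	Transgelin-2	-4.7
Drug resistance	PSAT	Phosphoserine aminotransferase (EC 2.6.1.52)	-3.4
Cellular adhesion	PPIB	Peptidyl-prolyl cis-trans isomerase B (cyclophilin B)	-4.5
Cellular adhesion	FN1 FN	Fibronectin (Cleaved into: Anastellin)	-2.9
Cellular adhesion	VCL	Vinculin (Metavinculin)	-2.8
Cancer stem cells	CD109	CD109 antigen	-5.0
Cancer stem cells	ANPEP	Aminopeptidase N	-2.8
Immune response	LTA4H	Leukotriene A-4 hydrolase	-4.7
Immune response	AEBP1	Adipocyte enhancer-binding protein 1	-3.2
Cellular invasion	PLEC	Plectin	-6.7
Angiogenesis	TIE1	Tyrosine-protein kinase receptor Tie-1 (EC 2.7.10.1)	-3.4
Epithelial-Mesenchymal Transition	DRIP4	Dopamine receptor interacting protein 4	-2.8
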