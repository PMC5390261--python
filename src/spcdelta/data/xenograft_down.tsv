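category	gene	description	rsc
Cellular growth	BCAT1	Branched chain amino acid aminotransferase	-10.1
Cellular growth	PPP1CB	Serine/threonine-protein phosphatase PP1-beta subunit	-7.4
Cellular growth	MTHFD1L	Monofunctional C1-tetrahydrofolate synthase	-5.6
Cellular growth	RPL13	60S ribosomal protein L13	-4.7
Cellular growth	CAP1 hCG_2033246	Adenylyl cyclase-associated protein	-4.6
Cellular growth	TMPO (LAP2)	Lamina-associated polypeptide 2, isoform alpha Thymopoietin isoform alpha	-3.2
Cellular growth	CLTC	Calathrin heavy chain 2	-2.7
Cellular growth	HSPA1A	Heat shock 70 kDa protein 1A/1B	-1.3
Cellular growth	HSP90AB1	Heat shock protein HSP 90-beta	-1.3
Cellular growth	PABPC4	Poly(A) binding protein 4	-1.3
Cellular growth	HIST1H2BD	Histone H2B type 1-D	-1.3
Cellular invasion	PDLIM1	LIM domain protein 1	-10.1
Cellular invasion	FAM49B	Protein FAM49B	-7.6
Cellular invasion	DPYSL3	Dihydropyrimidinase-related protein 3	-6.5
Cellular invasion	GNAI3	Guanine nucleotide-binding protein G subunit alpha 3	-4.7
Cellular invasion	PLEC	Plectin	-3.2
Cellular invasion	ANXA6	Annexin A6	-2.9
Cellular invasion	CA3	Carbonic anhydrase 3 (EC 4.2.1.1) (Carbonic anhydrase III) (CA-III)	-1.7
Cellular invasion	ANXA2	Annexin A2	-1.6
Cellular invasion	ALDOA	Fructose-bisphosphate aldotase A	-1.4
Cellular invasion	ANXA1	Annexin A1	-1.4
Cellular invasion	FKBP1A	Peptidyl-prolyl cis-trans isomerase	-1.1
Drug resistance	CAPN2	Calpain-2	-9.1
Drug resistance	DYNC1H1	Cytoplasmic dynein 1 heavy chain 1	-8.5
Drug resistance	PSMD1	26S proteasome regulatory subunit RPN2	-7.4
Drug resistance	PRKDC	DNA-dependent protein kinase catalytic subunit	-3.9
Drug resistance	TGM2	Protein -glutamine gamma-glutamyltransferase 2	-2.7
Drug resistance	HMGB1	High mobility group protein B1	-1.7
Drug resistance	PEBP1(RKIP)	Phosphatidylethanolamine-binding protein 1	-1.7
Drug resistance	MDH2	Malate dehydrogenase	-1.5
Drug resistance	HSP90AA1	Heat shock protein HSP 90-alpha	-1.3
Apoptosis	RLI	RNase L inhibitor	-8.1
Apoptosis	SLC25A6	ADP/ATP translocase 3 (ANT3)	-7.4
Apoptosis	LRPPRC	Leucine-rich PPR motig containing protein	-5.1
Apoptosis	SMC3	Structural maintenance of chromosome 3	-4.7
Apoptosis	COPA	Coatomer subunit alpha	-4.6
Apoptosis	MAGED2	Melanoma-associated antigen D2	-3.8
Apoptosis	NT5E (CD73)	5′-nucleotidase	-1.3
Cancer stem cells	CD109	Cluster of differentiation 109	-12.8
Cancer stem cells	PDHB	Pyruvate dehydrogenase E1 component subunit beta	-11.9
Cancer stem cells	ALDH18A1	Aldehyde dehydrogenase family 18 member A1	-3.8
Cancer stem cells	NES hCG_1999207	Nestin isoform CRA	-1.1
Cytoskeletal	TUBB2A	Tubulin beta-2A chain	-78.1
Cytoskeletal	CD2AP	Adaptor protein CMS	-6.5
Cytoskeletal	TUBB4A	Tubulin beta 4 A chain	-1.9
Cytoskeletal	TUBB5	Tubulin beta 5 chain	-1.7
Cellular adhesion	FN1 FN	Fibronectin (Cleaved into: Anastellin)	-55.4
Cellular adhesion	ILK	Integrin-linked protein kinase	-5.6
Cellular adhesion	ITGA2	Integrin alpha-2	-2.9
Cellular metabolism	HIST2H2BE	Histone H2B type 2-E	-46.3
Cellular metabolism	PFKP	Phosphofructo-1-kinase isozyme C	-10.1
Cellular metabolism	YARS2	Tyrosyl tRNA synthetase	-3.8
Epithelial-Mesenchymal Transition	TGFB1	Transforming growth factor-beta-induced protein	-12.8
Epithelial-Mesenchymal Transition	HNRNPM	Heterogeneous ribonucleoprotein M	-5.8
Epithelial-Mesenchymal Transition	PLS3	Plastin-3	-4.7
Transcriptional regulation	RUVBL2	RuvB-like 2 (EC 3.6.4.12) (48 kDa TATA box-binding protein-interacting protein)	-7.4
Transcriptional regulation	COPS7A	Signalosome subunit 7a	-5.6
Transcriptional regulation	HNRNPD	Heterogeneous nuclear ribonucleoprotein D0 (hnRNP D0) (AU-rich element RNA-binding protein 1)	-1.5
DNA repair	RECQL	ATP-dependant DNA helicase Q1	-11.0
DNA repair	UBA1	Ubiquitin-activating enzyme E1	-1.1
Tumour suppression	MAP1B	Microtubule-associated protein 1B	-5.6
Tumour suppression	AHNAK	Desamoyokin	-3.5
Tumour suppression	OGDH	2-oxoglutarate dehydrogenase	-1.1
Angiogenesis	TXNRD1	Thioredoxin reductase 1	-4.7
Angiogenesis	AARS	Alanine tRNA ligase	-4.7
Protein transport	VPS35	Vacuolar protein sorting-associated protein 35	-3.0
Protein transport	EEA1	Early endosome antigen 1	-2.2
Extracellular matrix	FN1	Fibronectin 1 Protein	-57.2
Carcinogen detoxification	CYB5R3	NADH-cytochrome b5 reductase 3 (Diaphorase-1)	-14.6
Immune Response	LTA4H	Leukotriene A-4 hydrolase	-10.6
Cellular migration/motility	KTN1	KTN1 protein (highly similar to Kinectin)	-5.6
Unknown function	TMPO hCG_2015322	Thymopentin isoform CRA_d	-2.7
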