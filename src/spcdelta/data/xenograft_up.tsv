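category	gene	description	rsc
Cellular metabolism	GOT1	Aspartate aminotransferase	2.0
Cellular metabolism	PYGB	Phosphorylase (EC 2.4.1.1)	1.5
Cellular metabolism	GOT2	Glutamic-oxaloacetic transaminase 2	1.1
Cellular metabolism	IDH2	Isocitrate dehydrogenase	2.5
Cellular metabolism	ATP5O	ATP synthase subunit O	1.3
Cellular growth	EIF42A	Eukaryotic translation initiation factor 4A2	5.9
Cellular growth	CKB	Creatine kinase B-type	3.7
Cellular growth	PCBP2 hCG_2017557	Poly(RC) binding protein 2	1.3
Cellular growth	TOMM34	Mitochondrial import receptor subunit TOM34	1.3
Apoptosis	POTEF	POTE ankyrin domain family member F	23.0
Apoptosis	HSPH1	Heat shock protein 105 kDa	1.5
Apoptosis	HNRNPH3	Heterogeneous nuclear ribonucleoprotein H3	1.4
Apoptosis	COMT	Catechol-O-methyltransferase	1.1
Tumour suppression	AMY2A	Alpha amylase	7.3
Tumour suppression	HBB	Mutant beta-globin	1.9
Tumour suppression	KRBA2	KRAB-A domain-containing protein	1.7
Tumour suppression	TPM1	Tropomyosin-1	1.2
Oxidative stress response	NUDT5	ADP-sugar pyrophosphatase	3.1
Oxidative stress response	DNAJB11	DnaJ homolog subfamily B member 11	1.3
Oxidative stress response	HBA1	Alpha-globin	1.2
Oxidative stress response	KPNA3	Karyopherin subunit alpha-3	1.0
Cytoskeletal	NEB	Nebulin	1.9
Cytoskeletal	TPM2	Tropomyosin-2	1.1
Calcium homeostasis	ATP2A1	Sarcoplasmic/endoplasmic reticulum calcium ATPase 1	5.6
Calcium homeostasis	ATP2A2	Sarcoplasmic/endoplasmic reticulum calcium ATPase 2	4.1
Prognosticator of survival	ALB	Serum albumin	3.7
Prognosticator of survival	HP	Haptoglobin (Zonulin)	3.0
Drug resistance	COL6A3	Collagen alpha-3(VI) chain	3.7
Drug resistance	TPI1	Triosephosphate isomerase 1	1.0
Iron transport	TF	Transferrin	3.7
Angiogenesis	FMOD	Fibromodulin	3.7
Cancer stem cells	ANPEP	Aminopeptidase N	1.1
mRNA regulation	NHP2L1	NHP2-like protein 1	2.1
Cellular adhesion	PRELP	Prolargin	2.0
Protein synthesis	RPS17L	40S ribosomal protein S17	1.7
Immune response	FLNC	Filamin-C	1.3
Cellular migration/motility	BGN	Biglycan	1.2
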