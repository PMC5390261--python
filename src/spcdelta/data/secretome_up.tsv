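category	gene	description	rsc
Cytoskeletal	TUBB2C	Tubulin beta-2C	2.3
Cytoskeletal	TUBB4A	Tubulin beta-4 chain	2.5
Cytoskeletal	TUBB5	Tubulin beta-5 chain	1.7
Cytoskeletal	TUBB6	Tubulin beta-6 chain	2.1
Cytoskeletal	ACTC1	Actin, alpha cardiac muscle 1	2.3
Cytoskeletal	ACTB	Beta Actin	2.3
Tumour suppression	HBB	Mutant beta-globin	5.0
Tumour suppression	APOA1	Apolipoprotein A1	4.3
Tumour suppression	ITIH3	Inter-alpha-trypsin inhibitor heavy chain H3	3.3
Tumour suppression	ITIH2	Inter-alpha (Globulin) inhibitor H2	3.1
Tumour suppression	A2M	Alpha-2-macroglobulin	3.3
Cellular growth/survival	HSP90AA1	Heat shock protein HSP 90-alpha	2.0
Cellular growth/survival	SERPINE1	Plasminogen activator inhibitor	1.8
Cellular growth/survival	HSPA8	Heat shock cognate 71 kDa protein	1.6
Cellular growth/survival	HSP90AB1	Heat shock protein HSP 90-beta	1.5
Oxidative stress response	GSTP1	Glutathione S-transferase P	3.3
Oxidative stress response	HPX	Hemopexin	2.9
Oxidative stress response	HBA1	Hemoglobin subunit alpha	2.7
Prognosticator of survival	ALB	Serum albumin	4.3
Prognosticator of survival	AFP	Alpha-fetoprotein	3.1
Immune response	PTX3	Pentraxin-related protein PTX3	4.1
Immune response	C4A	Complement C4-A	2.7
Cellular invasion	ANXA1	Annexin A1	4.7
Cellular invasion	ANXA2	Annexin A2	3.3
Estrogen-induced malignancy	SERPINA7	Thyroxine-binding globulin	4.7
Angiogenesis	APOB	Apolipoprotein B-100	3.9
Apoptosis	POTEF	POTE ankyrin domain family member F	2.6
Iron transport	TF	Transferrin	2.5
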