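category	gene	description	rsc
Cytoskeletal	PLS1	Plastin-1	7.1
Cytoskeletal	TWF1	Twinfilin-1	5.1
Cytoskeletal	EPB41L2	Erythrocyte membrane protein band 4.1-like 2	4.5
Tumour suppression	APOA1	Apolipoprotein A-1	5.1
Tumour suppression	ETF1	Eukaryotic release factor 1	2.3
Tumour suppression	AHNAK	Desmoyokin	1.8
Cellular growth/survival	TFRC	Transferrin receptor protein 1 (CD71)	2.9
Cellular growth/survival	DDX3X	ATP-dependant RNA helicase DDX3X	2.6
Cellular growth/survival	EIF4A2	Eukaryotic initiation factor 4A2	1.8
Drug resistance	TYMS	Thymidylate synthase (EC 2.1.1.45)	5.1
Drug resistance	ATP1A1	Sodium pump subunit alpha-1	1.8
Lipid metabolism	NCEH1	Neutral cholestrol ester hydrolase 1	3.8
Lipid metabolism	PRIC295	Peroxisome proliferator activated receptor interacting complex protein	2.6
Extracellular matrix	PLOD2	Procollagen-lysine, 2-oxoglutarate 5-dioxygenase 2	2.1
Drug sensitivity	PEBP1 (RKIP)	Phosphatidylethanolamine-binding protein 1	1.9
Immune response	FLNC	Filamin-C	1.4
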