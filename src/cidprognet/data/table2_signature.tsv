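feature_no	gene_symbol	myb_direction	mybl_direction	annotation
2654	APOM	Up	none	Protein
714	IQCK	Up	Down	SRC-3 binding protein
9472	POU2F1	Up	Down	TF
20014	PPP1R9A	Up	none	Phosphatase
11991	POU2F1	Up	Down	TF
7164	ZFP112(ZNF228)	Up	Down	Zinc finger protein
4051	TMC5	Up	Down	Transmembrane channel-like protein
9673	STK36	Up	Down	Serine/threonine kinase
1509	TMEM87B(CR621710)	Up	none	Transmembrane protein
6481	TTC19	Up	Down	Roles in protein-protein interactions
10396	BC009926	Up	Down	The inner mitochondrial membrane protein
20295	PAH	Up	none	amino acid metabolism
3096	SALL2	Up	none	TF and putative tumor suppressor
17750	TBC1D9	Up	Down	Multidrug resistance gene 1(MDR1)
20917	NTN4	Up	Down	Good prognostic factor
8570	CATSPER2	Up	none	Ion channel
6691	ANAPC4	Up	Down	Chromosome replication
10334	THSD4	Up	Down	A disintegrin and metalloproteinase
9326	ABAT	Up	Down	Aminotransferase
15762	NBPF4(ENST00000370040)	Up	none	Undefined function
10024	XBP1	Up	Down	TF
10998	PMS2CL	Up	none	Mismatch repair gene
11119	TGM2	Down	none	Metabolism
3069	ACOT7	Down	Up	Fatty acid metabolism
1039	GNAI2	Down	none	G protein
19802	PKMYT1	Down	Up	Kinase
20037	GAPDH	Down	Up	Candidate target for cancer treatment; proliferation and metastasis; glycolysis.
5918	MAP1S	Down	none	Morphology; microtubule associated protein
956	CCDC124	Down	Up	Undefined function
21198	GNB2	Down	none	G protein
13619	TOMM40	Down	none	Enzyme
18840	NFKBIL2	Down	none	A negative regulator of NFKB mediated transcription; the maintenance of genome stability; may cause chemoresistance
4681	RAB42	Down	Up	Putative Ras-related protein related to cell proliferation
3891	MAF1	Down	Up	Control transcription initiation
21760	ZNF598	Down	Up	Undefined function
17698	EIF5A	Down	none	Translation
7939	SLC25A1	Down	Up	Cellular component
7824	PCBP3	Down	none	Posttranscriptional activities
16475	DUSP7	Down	Up	Phosphatase
17776	PICK1	Down	none	Signaling molecule; poor prognosis; promote tumor growth
3073	RANGAP1	Down	Up	G protein signaling; a new target for cancer chemotherapy
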