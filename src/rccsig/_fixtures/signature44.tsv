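gene_symbol	description	cytoband	source_class	rank
ABCA8	ATP-binding cassette, sub-family A (ABC1), member 8	17q24
AKR1C2	aldo-keto reductase family 1, member C2	10p15-p14
ALDOB	aldolase B, fructose-bisphosphate	9q21.3-q22.2
ANGPTL4	angiopoietin-like 4	19p13.3
AQP6	aquaporin 6, kidney specific	12q13
ASS1	argininosuccinate synthase 1	9q34.1
ATP6V0A4	ATPase, H+ transporting, lysosomal V0 subunit a4	7q34
C7	complement component 7	5p13
CALB1	calbindin 1, 28 kDa	8q21.3
CLDN8	claudin 8	21q22.11
CRYAB	crystallin, alpha B	11q22.3-q23.1
DEFB1	defensin, beta 1	8p23.1
DHRS2	dehydrogenase/reductase (SDR family) member 2	14q11.2
FLRT3	fibronectin leucine rich transmembrane protein 3	20p11
FOSB	FBJ murine osteosarcoma viral oncogene homolog B	19q13.32
GSTA1	glutathione S-transferase alpha 1	6p12.1
HILPDA	hypoxia inducible lipid droplet-associated	7q32.1
IGFBP1	insulin-like growth factor binding protein 1	7p12.3
IGFBP6	insulin-like growth factor binding protein 6	12q13
KRT7	keratin 7, type II	12q13.13
LCN2	lipocalin 2	9q34
MAL	mal, T-cell differentiation protein	2q11.1
MAOB	monoamine oxidase B	Xp11.23
MMP7	matrix metallopeptidase 7 (matrilysin, uterine)	11q21-q22
MT1G	metallothionein 1G	16q13
NDUFA4L2	NADH dehydrogenase (ubiquinone) 1 alpha subcomplex, 4-like 2	12q13.3
NNMT	nicotinamide N-methyltransferase	11q23.1
PAH	phenylalanine hydroxylase	12q22-q24.2
PCP4	Purkinje cell protein 4	21q22.2
PLIN2	perilipin 2	9p22.1
RHCG	Rh family, C glycoprotein	15q25
RNF128	ring finger protein 128, E3 ubiquitin protein ligase	Xq22.3
S100A2	S100 calcium binding protein A2	1q21
SERPINA5	serpin peptidase inhibitor, clade A (alpha-1 antiproteinase, antitrypsin), member 5	14q32.1
SFTPB	surfactant protein B	2p12-p11.2
SLC12A1	solute carrier family 12 (sodium/potassium/chloride transporter), member 1	15q15-q21.1
SLC18A2	solute carrier family 18 (vesicular monoamine transporter), member 2	10q25
STAP1	signal transducing adaptor family member 1	4q13.2
TACSTD2	tumor-associated calcium signal transducer 2	1p32
TFPI2	tissue factor pathway inhibitor 2	7q22
TMEM255A	transmembrane protein 255A	Xq24
UMOD	uromodulin	16p12.3
VCAN	versican	5q14.3
ZNF395	zinc finger protein 395	8p21.1
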