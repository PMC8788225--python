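family	description	anopheles_gambiae_genes	anopheles_gambiae_ogs	drosophila_melanogaster_genes	drosophila_melanogaster_ogs
GALE	Galectins: beta-galactoside-binding pattern recognition receptors	9	6	6	5
GNBP	Gram-negative binding proteins (beta-1,3-glucan-binding PRRs)	7	3	3	3
PGRP	Peptidoglycan recognition proteins	7	5	12	6
SCRA	Scavenger receptors class A	5	5	5	4
SCRB	Scavenger receptors class B	13	10	14	9
CTL	C-type lectins	25	20	37	29
FREP	Fibrinogen-related proteins	38	15	13	6
LRIM	Leucine-rich repeat immune proteins	24	20	0	0
ML	MD-2-like lipid recognition proteins	16	7	8	5
NIMROD	Nimrod phagocytosis receptors	3	3	12	8
TEP	Thioester-containing proteins	10	5	5	5
IMDSIG	Imd pathway signal transducers	9	9	10	10
IMDMOD	Imd pathway modulators	6	6	6	6
JASTSIG	JAK/STAT pathway signal transducers	3	3	6	6
JASTMOD	JAK/STAT pathway modulators	3	3	4	4
TOLLSIG	Toll pathway signal transducers	5	5	6	6
TOLLMOD	Toll pathway modulators	8	8	8	8
CASP	Caspases	15	6	7	5
CLIPA	CLIP-domain serine protease homologs, subfamily A	20	13	12	10
CLIPB	CLIP-domain serine proteases, subfamily B	27	20	15	13
CLIPC	CLIP-domain serine proteases, subfamily C	8	6	7	7
CLIPD	CLIP-domain serine proteases, subfamily D	9	8	10	10
CLIPE	CLIP-domain serine proteases, subfamily E	9	7	3	3
IAP	Inhibitors of apoptosis	8	5	4	4
SRPN	Serine protease inhibitors (serpins)	18	16	30	20
AMP	Antimicrobial peptides	9	8	10	5
LYS	Lysozymes	7	1	17	3
PPO	Prophenoloxidases	9	1	3	1
GPX	Glutathione peroxidases	2	2	2	2
HPX	Heme peroxidases	15	10	10	9
TPX	Thioredoxin peroxidases	5	5	6	6
SOD	Superoxide dismutases	4	4	4	4
APHAG	Autophagy-related genes	19	19	22	22
SRRP	Small regulatory RNA pathway members	28	23	22	20
SPZ	Spaetzle-like cytokines	5	5	6	6
TOLL	Toll receptors	12	6	9	6
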