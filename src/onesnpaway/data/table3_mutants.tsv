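# Transcription of the published table of lambda Rz and Rz1 lysis-defective
# (and engineered control) alleles, one row per allele.
# change_type transcribes the printed transition (->) / transversion (>>)
# glyphs for substitution rows; it is a cross-check only -- the package
# recomputes ts/tv from codons when a CDS is supplied. Nonsense rows carry
# their stop type in the alt column instead.
# lysis: defective = blocks lysis (printed "-"), functional = supports lysis ("+").
# isolates 0 <=> site_directed.
gene	codon_position	ref_aa	alt	isolates	lysis	source	change_type
Rz	1	M	K	1	defective	random	transition
Rz	4	V	artificial-TMD(4-24)	0	functional	site_directed
Rz	14	C	R	2	defective	random	transition
Rz	19	L	P	2	defective	random	transition
Rz	20	S	P	0	functional	site_directed	transition
Rz	36	Q	P	0	functional	site_directed	transition
Rz	50	A	P	0	functional	site_directed	transition
Rz	57	R	C	2	defective	random	transition
Rz	59	R	C	1	defective	random	transition
Rz	61	V	A	1	defective	random	transition
Rz	62	A	P	0	defective	site_directed	transition
Rz	64	L	H	2	defective	random	transversion
Rz	64	L	P	3	defective	random	transition
Rz	64	L	R	1	defective	random	transversion
Rz	65	D	G	2	defective	random	transition
Rz	65	D	N	1	defective	random	transition
Rz	65	D	V	1	defective	random	transversion
Rz	66	A	P	1	defective	random	transversion
Rz	67	K	N	1	defective	random	transversion
Rz	70	K	E	1	defective	random	transition
Rz	72	L	F	1	defective	random	transversion
Rz	72	L	S	1	defective	random	transition
Rz	73	A	P	1	defective	random	transversion
Rz	73	A	V	1	defective	random	transition
Rz	77	A	P	1	defective	random	transversion
Rz	82	L	P	1	defective	random	transition
Rz	83	R	P	1	defective	random	transversion
Rz	86	V	G	1	defective	random	transversion
Rz	88	A	P	2	defective	random	transversion
Rz	91	R	P	2	defective	random	transversion
Rz	93	L	S	3	defective	random	transition
Rz	100	Q	(Gly-Ser)8-linker(100-115)	0	functional	site_directed
Rz	107	T	P	0	functional	site_directed	transition
Rz	125	R	P	0	functional	site_directed	transition
Rz	127	Y	N	1	defective	random	transversion
Rz	134	L	P	3	defective	random	transition
Rz	141	L	P	1	defective	random	transition
Rz	143	G	R	1	defective	random	transversion
Rz	147	Y	H	1	defective	random	transition
Rz	147	Y	C	2	defective	random	transition
Rz	150	E	R	0	defective	site_directed	transition
Rz	150	E	G	0	defective	site_directed	transition
Rz	151	Q	R	2	defective	random	transition
Rz	151	Q	K	1	defective	random	transversion
Rz	151	Q	P	0	functional	site_directed	transition
Rz	151	Q	X(Ochre)	0	defective	site_directed
Rz	152	C	X(Ochre)	0	defective	site_directed
Rz	153	R	X(Ochre)	0	functional	site_directed
Rz1	1	M	K	1	defective	random	transition
Rz1	12	M	R	3	defective	random	transversion
Rz1	19	G	C	3	defective	random	transversion
Rz1	20	C	S	5	defective	random	transversion
Rz1	20	C	R	1	defective	random	transition
Rz1	20	C	F	2	defective	random	transversion
Rz1	20	C	Y	3	defective	random	transition
Rz1	25	S	(Gly-Ser)3-linker(25-30)	0	functional	site_directed
Rz1	32	P	Q	1	defective	random	transversion
Rz1	33	P	L	1	defective	random	transition
Rz1	35	P	H	3	defective	random	transversion
Rz1	36	P	Q	3	defective	random	transversion
Rz1	36	P	L	2	defective	random	transition
Rz1	39	I	V	1	defective	random	transition
Rz1	42	P	S	1	defective	random	transition
Rz1	44	P	S	1	defective	random	transition
Rz1	45	D	K	0	functional	site_directed	transition
Rz1	46	W	C	1	defective	random	transversion
Rz1	46	W	R	2	defective	random	transition
Rz1	50	L	R	1	defective	random	transversion
Rz1	50	L	P	7	defective	random	transition
Rz1	54	I	N	1	defective	random	transversion
Rz1	54	I	X(Ochre)	0	defective	site_directed
Rz1	55	S	X(Amber)	0	functional	site_directed
Rz1	56	P	X(Opal)	0	functional	site_directed
Rz1	57	S	X(Ochre)	0	functional	site_directed
Rz1	58	E	K	1	defective	random	transition
Rz1	58	E	X(Ochre)	0	functional	site_directed
Rz1	59	R	E	0	functional	site_directed	transition
Rz1	60	G	X(Ochre)	0	functional	site_directed
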