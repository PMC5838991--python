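patient_id	chrom	pos	ref	alt	gene	variant_class	protein_change	cdna_change	vaf	alt_reads	depth	cosmic	popfreq_1000g	popfreq_exac	sift	clinvar_sig
7	chr16	3781589	G	A	CREBBP	stopgain	p.Q540X	c.C1618T	0.28	84	300	True
3	chr12	121432117	A	AC	HNF1A	frameshift_indel	p.288fs	c.864_865insC	0.22	66	300	False
8	chr2	209113112	C	T	IDH1	missense	p.R132H	c.G395A	0.31	93	300	True
6	chr17	29665051	A	T	NF1	splice		c.A3975-2T	0.19	57	300	False
12	chr3	178936091	G	A	PIK3CA	missense	p.E545K	c.G1633A	0.35	105	300	True
2	chr3	178951973	A	G	PIK3CA	missense	p.M1043 V	c.A3127G	0.26	78	300	True
6	chr10	89692905	AG	A	PTEN	frameshift_indel	p.R142fs	c.425delG	0.24	72	300	False
13	chr17	7578190	T	C	TP53	missense	p.Y234C	c.A701G	0.42	126	300	True
9	chr17	7577121	G	A	TP53	missense	p.R273C	c.C817T	0.38	114	300	True
2	chr17	7578263	G	A	TP53	stopgain			0.33	99	300	True
7	chr17	7577559	G	A	TP53	stopgain			0.29	87	300	True
2	chr17	7574003	GC	G	TP53	frameshift_indel			0.27	81	300	False
5	chr17	7578212	GA	G	TP53	frameshift_indel			0.36	108	300	False
12	chr17	7579470	CG	C	TP53	frameshift_indel			0.30	90	300	False
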