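patient_id	chrom	pos	ref	alt	gene	variant_class	protein_change	cdna_change	vaf	alt_reads	depth	cosmic	popfreq_1000g	popfreq_exac	sift	clinvar_sig
1	chr2	47630514	G	A	MSH2	missense	p.V78I	c.G232A	0.24	72	300	False			deleterious
2	chr12	133234827	C	G	POLE	missense	p.E991Q	c.G2971C	0.31	93	300	False			deleterious
2	chr2	190656578	C	T	PMS1	missense	p.A6V	c.C17T	0.27	81	300	False			deleterious
2	chr2	47690169	G	A	MSH2	missense	p.A600T	c.G1798A	0.29	87	300	False			deleterious
3	chr2	47693796	A	G	MSH2	missense	p.Q629R	c.A1886G	0.22	66	300	False			neutral	Not_provided;benign
3	chr3	37083775	C	A	MLH1	missense	p.Q701K	c.C2101A	0.25	75	300	False			neutral	Likely_benign;pathogenic
4	chr2	47710100	C	T	MSH2	stopgain	p.R929X	c.C2785T	0.33	99	300	False				Pathogenic
4	chr2	47672686	A	G	MSH2	missense	p.T564A	c.A1690G	0.26	78	300	False			neutral	Benign
5	chr7	6026988	C	G	PMS2	missense	p.H435Q	c.C1305G	0.21	63	300	False			neutral
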