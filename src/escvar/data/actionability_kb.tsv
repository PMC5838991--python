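gene	pattern_type	pattern_value	therapy	evidence_note	citation_tag
AKT1	amplification		mTOR inhibitors; AKT inhibitor MK2206	Response to mTOR inhibition and AKT inhibitor MK2206	preclinical
CREBBP	exact_protein_change	p.Q540X	HDAC inhibitors	Active clinical trial	clinical_trial
HNF1A	exact_protein_change	p.288fs	mTOR inhibitors	Response in in-vitro experiments	preclinical
IDH1	exact_protein_change	p.R132H	IDH1 and pan-IDH inhibitors	Active clinical trial	clinical_trial
MET	amplification		c-MET inhibitors	Response to c-MET inhibitors	clinical
NF1	splice_disruption	c.A3975-2T	MEK inhibitors	Possibly increased sensitivity to MEK inhibition	preclinical
PIK3CA	exact_protein_change	p.E545K	PI3K/AKT/mTOR inhibitors	Activating hotspot in the p110a catalytic subunit	clinical_trial
PIK3CA	exact_protein_change	p.M1043V	PI3K/AKT/mTOR inhibitors	Activating hotspot in the p110a catalytic subunit	clinical_trial
PIK3CA	amplification		PI3K/AKT/mTOR inhibitors	Pathway activation by copy-number gain	clinical_trial
PTEN	exact_protein_change	p.R142fs	PI3K/AKT/mTOR inhibitors	Loss of PTEN activates PI3K signaling	clinical_trial
TP53	exact_protein_change	p.Y234C	bevacizumab; pazopanib	Better response to bevacizumab in carcinoma and pazopanib in advanced sarcoma	clinical
TP53	exact_protein_change	p.R273C	bevacizumab; pazopanib	Better response to bevacizumab in carcinoma and pazopanib in advanced sarcoma	clinical
TP53	truncation_class	nonsense	bevacizumab; pazopanib	Better response to bevacizumab in carcinoma and pazopanib in advanced sarcoma	clinical
TP53	truncation_class	frameshift	bevacizumab; pazopanib	Better response to bevacizumab in carcinoma and pazopanib in advanced sarcoma	clinical
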