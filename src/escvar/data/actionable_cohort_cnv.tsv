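patient_id	chrom	start	end	gene	log2_ratio	call
3	chr14	105235686	105262088	AKT1	1.0	gain
7	chr7	116312444	116438440	MET	1.0	gain
13	chr3	178866311	178952497	PIK3CA	1.0	gain
7	chr3	178866311	178952497	PIK3CA	1.0	gain
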