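# Functional gene groups for pathway-level cohort profiling.
RTK: [MET, CSF1R, FLT3, FLT1, ERBB2, FGFR4, PDGFRB]
RAS_PI3K: [PIK3CA, AKT1, PTEN, NF1]
histone_modification: [EP300, CREBBP, KMT2A, KMT2B, KDM5A]
cell_cycle_dna_repair: [TP53, RB1, CCND1, CDKN2A]
NOTCH: [NOTCH1, FBXW7]
MMR_proofreading: [MSH2, MLH1, PMS1, PMS2, POLE]
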