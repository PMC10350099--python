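gene_id	essential	mrna_per_cell	protein_mean	protein_cv2
geneA	1	1.25	2400.0	0.046
geneB	1	0.083	310.0	0.69
geneC	0	0.01	12.0	2.1
geneD	0	0.0		
geneE	1	0.42	870.0	0.14
geneF	0	3.8	9800.0	0.012
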