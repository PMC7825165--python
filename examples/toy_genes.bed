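chr1	120000	130000	GENE_A
chr1	455000	470000	GENE_B
chr1	820000	840000	GENE_C
chr2	60000	75000	GENE_D
chr2	380000	400000	RXFP2_LIKE
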