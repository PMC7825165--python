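unit	group	count	duplication	deletion	both	length_mb	genome_pct	n_individuals
cnv	AMS_no	427844	12657	415187	.	1874.08	.	8
cnv	AMS_horn	428669	12545	416124	.	1868.48	.	8
cnv	CMS_horn	444221	12429	431792	.	1881.06	.	8
cnv	AHS_no	446870	12220	434650	.	1883.50	.	8
cnv	cohort	.	49851	1697753	.	.	.	32
cnvr	AMS_no	5233	705	4518	10	13.5	0.52	8
cnvr	AMS_horn	5297	725	4565	7	14.03	0.54	8
cnvr	CMS_horn	5394	694	4689	11	14.14	0.55	8
cnvr	AHS_no	5441	698	4735	8	14.39	0.56	8
cnvr	cohort	.	861	6345	22	56.06	2.17	32
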