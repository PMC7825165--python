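study	platform	breed_n	sample_n	cnvr_count	cnvr_length_mb	overlap_count
Fontanesi_2011	aCGH	6	11	135	10.56	17
Liu_2013	SNP50	3	327	238	60.35	132
Ma_2015	SNP50	8	160	111	13.76	31
Jenkins_2016	aCGH	6	30	3488	66.27	153
Zhu_2016	SNP600	3	110	490	81.04	219
Ma_2017	SNP600	1	48	1296	120.53	424
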