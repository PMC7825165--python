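chr1	100000	140000	prev_cnvr_1
chr1	300000	320000	prev_cnvr_2
chr1	700000	760000	prev_cnvr_3
chr2	50000	90000	prev_cnvr_4
chr2	350000	420000	prev_cnvr_5
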