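sample	target	role	replicate	ct
calib	cnvr_a	target	1	24.00
calib	cnvr_a	target	2	24.05
calib	cnvr_a	target	3	23.95
calib	cnvr_a	reference	1	20.00
calib	cnvr_a	reference	2	20.02
calib	cnvr_a	reference	3	19.98
calib	cnvr_b	target	1	25.00
calib	cnvr_b	target	2	25.03
calib	cnvr_b	target	3	24.97
calib	cnvr_b	reference	1	20.00
calib	cnvr_b	reference	2	20.01
calib	cnvr_b	reference	3	19.99
sheep1	cnvr_a	target	1	27.00
sheep1	cnvr_a	target	2	27.04
sheep1	cnvr_a	target	3	26.96
sheep1	cnvr_a	reference	1	20.00
sheep1	cnvr_a	reference	2	20.03
sheep1	cnvr_a	reference	3	19.97
sheep1	cnvr_b	target	1	24.00
sheep1	cnvr_b	target	2	24.02
sheep1	cnvr_b	target	3	23.98
sheep1	cnvr_b	reference	1	20.00
sheep1	cnvr_b	reference	2	20.01
sheep1	cnvr_b	reference	3	19.99
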