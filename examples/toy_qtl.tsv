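chr1	1	250000	Milk_yield
chr1	400001	650000	Carcass_weight
chr1	800001	1000000	Fecal_egg_count
chr2	1	200000	Wool_fibre_diameter
chr2	300001	500000	Horn_type
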