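taxon	reads	pmds_gt1_reads	depth	breadth_pct	ct5_pct	neg_delta
Ovis aries	214	6	0.75	59	11.7	1
Triticum aestivum	177	3	0.02	2.4	2.5	1
Vitis vinifera	101	8	0.01	0.8	14.5	1
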