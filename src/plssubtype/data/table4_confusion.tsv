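ssp	Basal-like	HER2-enriched	Luminal-A	Luminal-B	Normal breast-like	Unclassified
Basal-like	83	1	0	1	0	12
HER2-enriched	0	63	0	3	0	28
Luminal-A	0	3	130	8	0	24
Luminal-B	0	5	10	73	0	33
Normal breast-like	1	3	17	1	8	26
Unclassified	0	0	0	0	0	2
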