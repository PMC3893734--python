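ssp	Basal-like	HER2-enriched	Luminal-A	Luminal-B	Normal breast-like	Unclassified
Basal-like	57	0	0	0	0	0
HER2-enriched	0	26	0	0	0	9
Luminal-A	0	0	21	0	0	2
Luminal-B	0	1	0	6	0	5
Normal breast-like	0	0	0	0	12	0
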