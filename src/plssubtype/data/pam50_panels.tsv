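subtype	gene	weight
Basal-like	ANLN	0.271
Basal-like	CEP55	0.271
Basal-like	ESR1	-0.319
Basal-like	FOXA1	-0.417
Basal-like	FOXC1	0.370
Basal-like	GPR160	-0.297
Basal-like	KNTC2	0.303
Basal-like	MELK	0.270
Basal-like	MIA	0.296
Basal-like	TMEM45B	-0.323
HER2-enriched	ACTR3B	-0.316
HER2-enriched	BAG1	-0.083
HER2-enriched	BLVRA	0.317
HER2-enriched	CCNE1	-0.067
HER2-enriched	CDC20	-0.069
HER2-enriched	ERBB2	0.452
HER2-enriched	FGFR4	0.365
HER2-enriched	GRB7	0.470
HER2-enriched	MYC	-0.390
HER2-enriched	SFRP1	-0.343
Luminal-A	BIRC5	-0.299
Luminal-A	CDCA1	-0.294
Luminal-A	CENPF	-0.288
Luminal-A	EXO1	-0.293
Luminal-A	MAPT	0.352
Luminal-A	MYBL2	-0.328
Luminal-A	NAT1	0.421
Luminal-A	PTTG1	-0.299
Luminal-A	SLC39A6	0.339
Luminal-A	UBE2C	-0.296
Luminal-B	BCL2	-0.325
Luminal-B	CDH3	-0.667
Luminal-B	CXXC5	0.484
Luminal-B	EGFR	-0.316
Luminal-B	KIF2C	-0.050
Luminal-B	MDM2	0.027
Luminal-B	MKI67	-0.136
Luminal-B	ORC6L	-0.049
Luminal-B	PR	-0.143
Luminal-B	PHGDH	-0.529
Normal breast-like	CCNB1	-0.272
Normal breast-like	CDC6	-0.241
Normal breast-like	KRT14	0.350
Normal breast-like	KRT17	0.241
Normal breast-like	KRT5	0.276
Normal breast-like	MLPH	0.376
Normal breast-like	MMP11	-0.404
Normal breast-like	RRM2	-0.359
Normal breast-like	TYMS	-0.286
Normal breast-like	UBE2T	-0.374
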