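pop	Longlin	Leizhou	HainanBlack	DazuBlack	JiningGrey	Boer	AlashanCashmere
Longlin	0.0	0.116601	0.075297	0.0730351	0.0824533	0.126503	0.0868544
Leizhou	0.116601	0.0	0.0411077	0.0879101	0.0992719	0.187433	0.13665
HainanBlack	0.075297	0.0411077	0.0	0.0514138	0.0552972	0.0908222	0.0682161
DazuBlack	0.0730351	0.0879101	0.0514138	0.0	0.0650801	0.106479	0.0759338
JiningGrey	0.0824533	0.0992719	0.0552972	0.0650801	0.0	0.0945023	0.070164
Boer	0.126503	0.187433	0.0908222	0.106479	0.0945023	0.0	0.115508
AlashanCashmere	0.0868544	0.13665	0.0682161	0.0759338	0.070164	0.115508	0.0
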