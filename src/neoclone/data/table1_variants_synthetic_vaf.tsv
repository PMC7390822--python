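gene	protein_id	mutation	vaf
EGFR	EGFR_ctx	E746_A750del	0.30
TP53	TP53_ctx	A161T	0.30
DENND6B	DENND6B_ctx	R398Q	0.30
AP2M1	AP2M1_ctx	V377M	0.09
POLA2	POLA2_ctx	E448K	0.09
TTC37	TTC37_ctx	D95A	0.09
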