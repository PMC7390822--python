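gene	tpm
EGFR	85.0
TP53	24.0
DENND6B	6.5
AP2M1	31.0
POLA2	12.0
TTC37	3.2
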