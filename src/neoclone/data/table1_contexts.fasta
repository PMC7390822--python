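>EGFR_ctx gene=EGFR start=740
IPVAIKELREATSPKANK
>TP53_ctx gene=TP53 start=154
GTRVRAMAIYKQ
>DENND6B_ctx gene=DENND6B start=393
KALLKRLLKGVQKK
>AP2M1_ctx gene=AP2M1 start=370
KASENAIVWK
>POLA2_ctx gene=POLA2 start=440
FSYSDLSRE
>TTC37_ctx gene=TTC37 start=93
KDDLPGVYQK
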