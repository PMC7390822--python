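number	gene	mutation	clonality	mutant_peptide	ic50_mut	wt_peptide	ic50_wt
C1	EGFR	E746_A750del	clonal	IPVAIKTSPK	131.9	IPVAIKELRE	28,185.9
C2	EGFR	E746_A750del	clonal	AIKTSPKANK	404.4	AIKELREATS	37,251.5
C3	TP53	A161T	clonal	RVRAMTIYKQ	288.6	RVRAMAIYKQ	486.1
C4	TP53	A161T	clonal	GTRVRAMTIYK	165.5	GTRVRAMAIYK	251.6
C5	TP53	A161T	clonal	TRVRAMTIYK	30.7	TRVRAMAIYK	44
C6	TP53	A161T	clonal	RVRAMTIYK	16.1	RVRAMAIYK	20.9
C7	DENND6B	R398Q	clonal	QLLKGVQKK	498.5	RLLKGVQKK	165.1
C8	DENND6B	R398Q	clonal	KALLKQLLK	54.8	KALLKRLLK	71.5
C9	DENND6B	R398Q	clonal	KQLLKGVQK	420.6	KRLLKGVQK	17,851.5
S1	AP2M1	V377M	subclonal	KASENAIMWK	51.6	KASENAIVWK	91.8
S2	AP2M1	V377M	subclonal	ASENAIMWK	41.6	ASENAIVWK	68
S3	POLA2	E448K	subclonal	FSYSDLSRK	47.3	FSYSDLSRE	15,881.9
S4	TTC37	D95A	subclonal	KDALPGVYQK	171.6	KDDLPGVYQK	7,311.9
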