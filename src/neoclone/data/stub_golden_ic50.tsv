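peptide	allele	ic50_nm
IPVAIKTSPK	HLA-A*11:01	870.1843
AIKTSPKANK	HLA-A*11:01	1478.9992
RVRAMTIYKQ	HLA-A*11:01	1904.193
GTRVRAMTIYK	HLA-A*11:01	1037.6298
TRVRAMTIYK	HLA-A*11:01	2613.1667
RVRAMTIYK	HLA-A*11:01	1900.5516
QLLKGVQKK	HLA-A*11:01	851.1215
KALLKQLLK	HLA-A*11:01	877.0048
KQLLKGVQK	HLA-A*11:01	1475.8254
KASENAIMWK	HLA-A*11:01	1807.6665
ASENAIMWK	HLA-A*11:01	707.6632
FSYSDLSRK	HLA-A*11:01	1982.2796
KDALPGVYQK	HLA-A*11:01	4734.8523
IPVAIKELRE	HLA-A*11:01	920.9573
AIKELREATS	HLA-A*11:01	910.7281
RVRAMAIYKQ	HLA-A*11:01	1631.2548
GTRVRAMAIYK	HLA-A*11:01	1071.0022
TRVRAMAIYK	HLA-A*11:01	3028.4353
RVRAMAIYK	HLA-A*11:01	1600.3871
RLLKGVQKK	HLA-A*11:01	447.0879
KALLKRLLK	HLA-A*11:01	461.5601
KRLLKGVQK	HLA-A*11:01	1655.1218
KASENAIVWK	HLA-A*11:01	1590.0098
ASENAIVWK	HLA-A*11:01	1063.2958
FSYSDLSRE	HLA-A*11:01	1929.6154
KDDLPGVYQK	HLA-A*11:01	7906.3846
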