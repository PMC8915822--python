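substance,run_id,cv75_ug_ml,cd86_rfi_max_pct,cd54_rfi_max_pct,ec150_ug_ml,ec200_ug_ml
Nickel sulfate,1,218,371,2423,46,51
Nickel sulfate,2,162,262,1829,46,51
2-Mercaptobenzothiazole,1,166,510,526,85,59
2-Mercaptobenzothiazole,2,160,233,752,85,59
R(+)-Limonene,1,180,144,254,239,121
R(+)-Limonene,2,376,473,1012,239,121
Imidazolidinyl urea,1,37,462,690,42,31
Imidazolidinyl urea,2,42,214,463,42,31
Isopropanol,1,>1000,97,153,N/A,N/A
Isopropanol,2,>1000,114,176,N/A,N/A
Glycerol,1,>1000,139,132,N/A,N/A
Glycerol,2,>1000,72,122,N/A,N/A
Lactic acid,1,>1000,127,133,N/A,N/A
Lactic acid,2,>1000,92,181,N/A,N/A
4-Aminobenzoic acid,1,>1000,88,100,N/A,N/A
4-Aminobenzoic acid,2,>1000,102,197,N/A,N/A
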