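substance,in_vivo_class,expected_call,cv75_low,cv75_high,ec150_low,ec150_high,ec150_historically_negative,ec200_low,ec200_high,ec200_historically_negative
Nickel sulfate,S (moderate),Positive,30,500,,100,false,10,100,false
2-Mercaptobenzothiazole,S (moderate),Positive,30,400,10,,true,10,140,false
R(+)-Limonene,S (weak),Positive,20,,5,,true,,250,false
Imidazolidinyl urea,S (weak),Positive,25,100,20,90,false,20,75,false
Isopropanol,NS,Negative,5000,,5000,,false,5000,,false
Glycerol,NS,Negative,5000,,5000,,false,5000,,false
Lactic acid,NS,Negative,1500,5000,5000,,false,5000,,false
4-Aminobenzoic acid,NS,Negative,1000,,1000,,false,1000,,false
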