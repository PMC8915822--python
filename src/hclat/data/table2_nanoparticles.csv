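substance,size_nm,run_id,cv75_ug_ml,cd86_rfi_max_pct,ec150_ug_ml,cd54_rfi_max_pct,ec200_ug_ml
Silver,20,1,20.6,161,17,326,11
Silver,20,2,20.6,174,11,285,8
Silver,20,3,20.6,109,N/A,248,17
Silver,50,1,21.6,146,N/A,1205,8
Silver,50,2,21.6,109,N/A,169,N/A
Silver,50,3,21.6,181,8,880,6
Silver,80,1,20.8,260,8.0,10006,8
Silver,80,2,20.8,156,25,234,11
Silver,80,3,20.8,249,8,4381,8
Zinc Oxide,30-40,1,25.8,217,12,3922,10
Zinc Oxide,30-40,2,25.8,263,13,4622,11
Zinc Oxide,30-40,3,25.8,360,9,4721,11
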