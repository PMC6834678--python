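study,variant,kd_ph58_nm,kd_ph58_sd_nm,ph74_low_detectable,ph74_medium_detectable,ph74_high_detectable,kd_ph74_medium_nm,kd_ph74_high_nm
SPR_hFcRn,wt,550,50,0,0,0,,
SPR_hFcRn,DHS,110,20,0,0,0,,
SPR_hFcRn,YTE,23,1,0,1,1,4730,4290
SPR_hFcRn,LS,55,3,0,1,1,946,567
SPR_hFcRn,EDHY,28,,0,1,1,,
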