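study,variant,mean_h,sd_h,n
Tg276,wt,49.6,13.4,11
Tg276,DHS,290.9,25.6,11
Tg276,YTE,148.4,36.8,11
Tg276,LS,92.9,6.1,11
Scarlett,wt,92.1,12.3,6
Scarlett,DHS,381.0,85.0,6
Scarlett,YTE,236.8,20.8,6
Scarlett,LS,255.0,31.8,6
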