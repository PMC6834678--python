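study,variant,AUC_inf,CL,T_half_beta,V_ss,C_max
Tg276,wt,30.0,0.66,49.6,1.50,
Tg276,DHS,157.9,0.11,290.9,0.59,
Tg276,YTE,96.9,0.24,148.4,0.72,
Tg276,LS,84.4,0.21,92.9,0.60,
Scarlett,wt,74.8,0.27,92.1,0.65,29.9
Scarlett,DHS,356.8,0.056,381.0,0.25,45.6
Scarlett,YTE,238.1,0.084,236.8,0.33,35.5
Scarlett,LS,223.0,0.090,255.0,0.36,40.2
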