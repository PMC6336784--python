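treatment,index,component,point,lower,upper,n,n_boot,n_dropped
SPR-,I,T,0.030049549789546597,0.0057641407705126945,0.050157877564553636,6,500,0
SPR-,I_S,M,0.011342155009451791,0.0,0.024489795918367346,6,500,0
SPR-,I_P,P,0.022609786309206667,0.00439049503545292,0.03865324644067163,6,500,0
control,I,T,0.2315321452902578,0.04491185898869738,0.4723076427818205,6,500,0
control,I_S,M,0.09375,0.020761245674740473,0.14208333333333295,6,500,0
control,I_P,P,0.09858544933820478,0.005078141200646273,0.2431831039703496,6,500,0
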