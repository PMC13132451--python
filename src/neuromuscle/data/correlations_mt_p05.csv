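ci_name,cp_name,curve_type,domain_lo,domain_hi,coeffs
p0_5,twitch_ct,exponential_decay,0.13,0.65,108.8114835;4.572844544;15
p0_5,twitch_hrt,exponential_decay,0.13,0.65,79.66540887;3.475501196;12
p0_5,amp_ratio_long,linear,0.13,0.65,1.70659676;-0.05155094473
p0_5,amp_ratio_short,linear,0.13,0.65,0.266689232;0.04691139055
p0_5,c1i,linear,0.13,0.65,1.6;-0.6666666667
p0_5,c1n1,linear,0.13,0.65,1.2;2
p0_5,c1n4,linear,0.13,0.65,216.6666667;-111.1111111
p0_5,c2i,linear,0.13,0.65,2.5;0
p0_5,c2n1,linear,0.13,0.65,2.666666667;-1.111111111
p0_5,c2n4,linear,0.13,0.65,216.6666667;-111.1111111
p0_5,fv_vmax,linear,0.13,0.65,60;400
p0_5,fv_slope_short,linear,0.13,0.65,0.05;-0.05555555556
p0_5,fv_slope_len,linear,0.13,0.65,0.1194444444;-0.1296296296
p0_5,k_se,linear,0.13,0.65,-1.387778781e-17;0.6666666667
p0_5,a_muap,linear,0.13,0.65,0.2333333333;0.4444444444
p0_5,l_muap,linear,0.13,0.65,11.33333333;-8.888888889
p0_5,alpha_i,constant,0.13,0.65,0.3
p0_5,beta,constant,0.13,0.65,0.01
p0_5,gamma,constant,0.13,0.65,0.02
p0_5,fl_peak,constant,0.13,0.65,-1
p0_5,fl_hwhm,constant,0.13,0.65,14.985983
p0_5,fv_d0,constant,0.13,0.65,1.5
p0_5,p0_5,linear,0.13,0.65,0;1
p0_5,cv,linear,0.13,0.65,55;30
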