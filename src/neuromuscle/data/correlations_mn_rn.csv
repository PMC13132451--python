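ci_name,cp_name,curve_type,domain_lo,domain_hi,coeffs
r_n,tau_m,tabulated,1.0800000000000003,3.400000000000001,1.08;3.538141355;1.339790153;4.389228656;1.988130564;6.455755222;2.807017544;9.535781539;3.4;11.55021539
r_n,va_sd_dc,tabulated,1.0800000000000003,3.400000000000001,1.08;0.6024096386;1.339790153;0.6024096386;1.988130564;0.5970149254;2.807017544;0.625;3.4;0.625
r_n,va_sd_ac,tabulated,1.0800000000000003,3.400000000000001,1.08;0.4443634262;1.339790153;0.3981360671;1.988130564;0.3042902454;2.807017544;0.2441769086;3.4;0.2066753649
r_n,d_path,tabulated,1.0800000000000003,3.400000000000001,1.08;0.35;1.339790153;0.4;1.988130564;0.6;2.807017544;0.8;3.4;0.85
r_n,pic_mag,tabulated,1.0800000000000003,3.400000000000001,1.08;18.85596573;1.339790153;18.79253102;1.988130564;21.21562996;2.807017544;23.37314597;3.4;22.33148537
r_n,i_rheo,tabulated,1.0800000000000003,3.400000000000001,1.08;22.984375;1.339790153;20.3125;1.988130564;17.296875;2.807017544;15.59375;3.4;14.703125
r_n,va_ds_dc,constant,1.0800000000000003,3.400000000000001,0.9090909091
r_n,t_ahp_half,piecewise,1.0800000000000003,3.400000000000001,1.08;25.061786;2.2;44.2552113;2.2000001;68.65502959;3.4;72.5
r_n,pic_amp,constant,1.0800000000000003,3.400000000000001,1
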