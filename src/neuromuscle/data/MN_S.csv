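cell_kind,preset,parameter,group,unit,value
MN,S,g_m_s,RMP,mS/cm2,0.15
MN,S,g_m_d,RMP,mS/cm2,0.1
MN,S,g_c,RMP,mS/cm2,0.15
MN,S,c_m_s,RMP,uF/cm2,1.0
MN,S,c_m_d,RMP,uF/cm2,1.0
MN,S,g_naf_s,RMP,mS/cm2,40.0
MN,S,f_s,RMP,1,0.015
MN,S,g_cal_d,RMP,mS/cm2,0.08
MN,S,g_kca_d,RMP,mS/cm2,0.0
MN,S,s_nm,RMP,1,1.0
MN,S,d_path,RMP,mm,0.8
MN,S,e_leak,CMP,mV,-65.0
MN,S,e_na,CMP,mV,55.0
MN,S,e_k,CMP,mV,-80.0
MN,S,e_ca_d,CMP,mV,80.0
MN,S,ca_out,CMP,conc,2.0
MN,S,g_kdr_s,CMP,mS/cm2,35.0
MN,S,g_kca_s,CMP,mS/cm2,4.0
MN,S,g_nap_s,CMP,mS/cm2,0.0
MN,S,g_can_s,CMP,mS/cm2,0.5
MN,S,area_s,CMP,cm2,0.0005
MN,S,area_d,CMP,cm2,0.0045
MN,S,alpha_ca,CMP,conc/(uA/cm2)/ms,0.3
MN,S,k_ca,CMP,1/ms,1.0
MN,S,f_d,CMP,1,0.01
MN,S,kd_kca,CMP,conc,0.2
MN,S,ca_rest,CMP,conc,0.05
MN,S,vh_naf_m,CMP,mV,-35.0
MN,S,k_naf_m,CMP,mV,7.8
MN,S,vh_naf_h,CMP,mV,-50.0
MN,S,k_naf_h,CMP,mV,7.0
MN,S,vh_kdr,CMP,mV,-28.0
MN,S,k_kdr,CMP,mV,15.0
MN,S,vh_can_m,CMP,mV,-30.0
MN,S,k_can_m,CMP,mV,5.0
MN,S,vh_can_h,CMP,mV,-45.0
MN,S,k_can_h,CMP,mV,5.0
MN,S,tau_can_m,CMP,ms,4.0
MN,S,tau_can_h,CMP,ms,40.0
MN,S,vh_nap,CMP,mV,-50.0
MN,S,k_nap,CMP,mV,3.0
MN,S,vh_cal,CMP,mV,-48.0
MN,S,k_cal,CMP,mV,3.0
MN,S,tau_cal,CMP,ms,20.0
MN,S,dpath_slope_mv_per_mm,CMP,mV/mm,8.0
MN,S,dpath_ref_mm,CMP,mm,0.6
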