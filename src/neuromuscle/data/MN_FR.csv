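cell_kind,preset,parameter,group,unit,value
MN,FR,g_m_s,RMP,mS/cm2,0.2
MN,FR,g_m_d,RMP,mS/cm2,0.15
MN,FR,g_c,RMP,mS/cm2,0.2
MN,FR,c_m_s,RMP,uF/cm2,1.0
MN,FR,c_m_d,RMP,uF/cm2,1.0
MN,FR,g_naf_s,RMP,mS/cm2,45.0
MN,FR,f_s,RMP,1,0.03
MN,FR,g_cal_d,RMP,mS/cm2,0.07
MN,FR,g_kca_d,RMP,mS/cm2,0.0
MN,FR,s_nm,RMP,1,1.0
MN,FR,d_path,RMP,mm,0.6
MN,FR,e_leak,CMP,mV,-65.0
MN,FR,e_na,CMP,mV,55.0
MN,FR,e_k,CMP,mV,-80.0
MN,FR,e_ca_d,CMP,mV,80.0
MN,FR,ca_out,CMP,conc,2.0
MN,FR,g_kdr_s,CMP,mS/cm2,35.0
MN,FR,g_kca_s,CMP,mS/cm2,4.0
MN,FR,g_nap_s,CMP,mS/cm2,0.0
MN,FR,g_can_s,CMP,mS/cm2,0.5
MN,FR,area_s,CMP,cm2,0.0005
MN,FR,area_d,CMP,cm2,0.0045
MN,FR,alpha_ca,CMP,conc/(uA/cm2)/ms,0.3
MN,FR,k_ca,CMP,1/ms,1.0
MN,FR,f_d,CMP,1,0.01
MN,FR,kd_kca,CMP,conc,0.2
MN,FR,ca_rest,CMP,conc,0.05
MN,FR,vh_naf_m,CMP,mV,-35.0
MN,FR,k_naf_m,CMP,mV,7.8
MN,FR,vh_naf_h,CMP,mV,-50.0
MN,FR,k_naf_h,CMP,mV,7.0
MN,FR,vh_kdr,CMP,mV,-28.0
MN,FR,k_kdr,CMP,mV,15.0
MN,FR,vh_can_m,CMP,mV,-30.0
MN,FR,k_can_m,CMP,mV,5.0
MN,FR,vh_can_h,CMP,mV,-45.0
MN,FR,k_can_h,CMP,mV,5.0
MN,FR,tau_can_m,CMP,ms,4.0
MN,FR,tau_can_h,CMP,ms,40.0
MN,FR,vh_nap,CMP,mV,-50.0
MN,FR,k_nap,CMP,mV,3.0
MN,FR,vh_cal,CMP,mV,-48.0
MN,FR,k_cal,CMP,mV,3.0
MN,FR,tau_cal,CMP,ms,20.0
MN,FR,dpath_slope_mv_per_mm,CMP,mV/mm,8.0
MN,FR,dpath_ref_mm,CMP,mm,0.6
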