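cell_kind,preset,parameter,group,unit,value
MN,FF,g_m_s,RMP,mS/cm2,0.3
MN,FF,g_m_d,RMP,mS/cm2,0.22
MN,FF,g_c,RMP,mS/cm2,0.3
MN,FF,c_m_s,RMP,uF/cm2,1.0
MN,FF,c_m_d,RMP,uF/cm2,1.0
MN,FF,g_naf_s,RMP,mS/cm2,52.0
MN,FF,f_s,RMP,1,0.05
MN,FF,g_cal_d,RMP,mS/cm2,0.06
MN,FF,g_kca_d,RMP,mS/cm2,0.0
MN,FF,s_nm,RMP,1,1.0
MN,FF,d_path,RMP,mm,0.4
MN,FF,e_leak,CMP,mV,-65.0
MN,FF,e_na,CMP,mV,55.0
MN,FF,e_k,CMP,mV,-80.0
MN,FF,e_ca_d,CMP,mV,80.0
MN,FF,ca_out,CMP,conc,2.0
MN,FF,g_kdr_s,CMP,mS/cm2,35.0
MN,FF,g_kca_s,CMP,mS/cm2,4.0
MN,FF,g_nap_s,CMP,mS/cm2,0.0
MN,FF,g_can_s,CMP,mS/cm2,0.5
MN,FF,area_s,CMP,cm2,0.0005
MN,FF,area_d,CMP,cm2,0.0045
MN,FF,alpha_ca,CMP,conc/(uA/cm2)/ms,0.3
MN,FF,k_ca,CMP,1/ms,1.0
MN,FF,f_d,CMP,1,0.01
MN,FF,kd_kca,CMP,conc,0.2
MN,FF,ca_rest,CMP,conc,0.05
MN,FF,vh_naf_m,CMP,mV,-35.0
MN,FF,k_naf_m,CMP,mV,7.8
MN,FF,vh_naf_h,CMP,mV,-50.0
MN,FF,k_naf_h,CMP,mV,7.0
MN,FF,vh_kdr,CMP,mV,-28.0
MN,FF,k_kdr,CMP,mV,15.0
MN,FF,vh_can_m,CMP,mV,-30.0
MN,FF,k_can_m,CMP,mV,5.0
MN,FF,vh_can_h,CMP,mV,-45.0
MN,FF,k_can_h,CMP,mV,5.0
MN,FF,tau_can_m,CMP,ms,4.0
MN,FF,tau_can_h,CMP,ms,40.0
MN,FF,vh_nap,CMP,mV,-50.0
MN,FF,k_nap,CMP,mV,3.0
MN,FF,vh_cal,CMP,mV,-48.0
MN,FF,k_cal,CMP,mV,3.0
MN,FF,tau_cal,CMP,ms,20.0
MN,FF,dpath_slope_mv_per_mm,CMP,mV/mm,8.0
MN,FF,dpath_ref_mm,CMP,mm,0.6
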