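cell_kind,preset,parameter,group,unit,value
MT,MG,tau_1,RMP,ms,8.0
MT,MG,tau_2,RMP,ms,30.0
MT,MG,phi_1,RMP,1/mm,0.06
MT,MG,phi_3,RMP,1/mm,0.04
MT,MG,c1i,RMP,conc,1.2
MT,MG,c1n1,RMP,conc,2.4
MT,MG,c1n4,RMP,ms,150.0
MT,MG,c2i,RMP,1,2.5
MT,MG,c2n1,RMP,1,2.0
MT,MG,c2n4,RMP,ms,150.0
MT,MG,alpha_i,RMP,1,0.3
MT,MG,beta,RMP,1/mm,0.01
MT,MG,gamma,RMP,s/mm,0.02
MT,MG,p0_5,RMP,N,0.6
MT,MG,g_1,RMP,mm,-1.0
MT,MG,g_2,RMP,mm,18.0
MT,MG,a_0,RMP,1,0.25
MT,MG,b_0,RMP,mm/s,75.0
MT,MG,c_0,RMP,mm/s,12.0
MT,MG,d_0,RMP,1,1.5
MT,MG,k_se,RMP,N/mm,0.4
MT,MG,a_muap,RMP,mV,0.5
MT,MG,l_muap,RMP,ms,6.0
MT,MG,x_half,CMP,mm,-8.0
MT,MG,tau_fluct,CMP,ms,150.0
MT,MG,v_cap,CMP,mm/s,1000.0
MT,MG,ca_sat,CMP,conc,1.0
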