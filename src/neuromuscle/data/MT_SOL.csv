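cell_kind,preset,parameter,group,unit,value
MT,SOL,tau_1,RMP,ms,25.0
MT,SOL,tau_2,RMP,ms,90.0
MT,SOL,phi_1,RMP,1/mm,0.05
MT,SOL,phi_3,RMP,1/mm,0.03
MT,SOL,c1i,RMP,conc,1.5
MT,SOL,c1n1,RMP,conc,1.5
MT,SOL,c1n4,RMP,ms,200.0
MT,SOL,c2i,RMP,1,2.5
MT,SOL,c2n1,RMP,1,2.5
MT,SOL,c2n4,RMP,ms,200.0
MT,SOL,alpha_i,RMP,1,0.3
MT,SOL,beta,RMP,1/mm,0.01
MT,SOL,gamma,RMP,s/mm,0.02
MT,SOL,p0_5,RMP,N,0.15
MT,SOL,g_1,RMP,mm,-1.0
MT,SOL,g_2,RMP,mm,18.0
MT,SOL,a_0,RMP,1,0.25
MT,SOL,b_0,RMP,mm/s,30.0
MT,SOL,c_0,RMP,mm/s,5.0
MT,SOL,d_0,RMP,1,1.5
MT,SOL,k_se,RMP,N/mm,0.1
MT,SOL,a_muap,RMP,mV,0.3
MT,SOL,l_muap,RMP,ms,10.0
MT,SOL,x_half,CMP,mm,-8.0
MT,SOL,tau_fluct,CMP,ms,150.0
MT,SOL,v_cap,CMP,mm/s,1000.0
MT,SOL,ca_sat,CMP,conc,1.0
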