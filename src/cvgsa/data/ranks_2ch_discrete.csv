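estimator,sampler,E_min_lv,E_max_lv,tau_es_lv,tau_ep_lv,E_min_la,E_max_la,tau_es_la,tau_ep_la,Z_ao,R_mv,C_sas,R_sas,L_sas,C_sat,R_sat,L_sat,R_sar,R_scp,R_svn,C_svn
homma,sobol,17,18,4,1,19,20,9,15,14,13,11,7,8,5,10,6,3,2,16,12
homma,lattice,18,14,5,1,19,20,12,17,6,15,7,10,8,4,11,9,2,3,16,13
homma,golden,14,9,4,1,8,6,17,7,12,10,16,19,18,5,15,20,2,3,13,11
homma,uniform,1,3,10,2,14,9,19,12,20,4,15,18,17,11,13,16,8,7,6,5
homma,lhs,3,7,11,8,12,9,17,15,13,5,16,20,19,6,14,18,4,2,1,10
sobol,sobol,7,19,8,4,14,15,16,17,3,18,12,6,1,5,11,2,9,10,13,20
sobol,lattice,6,18,7,4,14,13,19,17,2,15,16,3,1,5,11,10,8,9,12,20
sobol,golden,6,19,8,7,14,16,18,17,5,15,11,4,1,3,2,12,9,10,13,20
sobol,uniform,9,20,6,7,1,15,17,18,4,16,2,5,3,12,8,13,11,10,14,19
sobol,lhs,6,20,5,4,16,9,15,7,2,17,18,3,1,12,8,13,11,10,14,19
jansen,sobol,5,20,4,3,16,17,12,15,1,14,7,2,18,6,10,8,9,11,13,19
jansen,lattice,5,20,4,3,16,17,12,15,1,14,7,2,18,6,11,8,9,10,13,19
jansen,golden,5,20,4,3,16,17,12,15,1,14,7,2,18,6,9,8,10,11,13,19
jansen,uniform,5,19,4,3,18,16,12,17,1,15,7,2,14,6,9,8,11,10,13,20
jansen,lhs,5,20,4,3,16,17,12,15,1,14,7,2,18,6,10,8,11,9,13,19
janon,sobol,5,20,4,3,16,17,12,15,1,14,7,2,18,6,10,8,9,11,13,19
janon,lattice,5,20,4,3,16,17,12,15,1,14,7,2,18,6,11,8,9,10,13,19
janon,golden,5,20,4,3,16,17,12,15,1,14,7,2,18,6,9,8,10,11,13,19
janon,uniform,5,19,4,3,18,16,12,17,1,15,7,2,14,6,9,8,11,10,13,20
janon,lhs,5,20,4,3,16,17,12,15,1,14,7,2,18,6,10,8,11,9,13,19
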