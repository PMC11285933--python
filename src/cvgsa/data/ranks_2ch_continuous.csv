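estimator,sampler,E_min_lv,E_max_lv,tau_es_lv,tau_ep_lv,E_min_la,E_max_la,tau_es_la,tau_ep_la,Z_ao,R_mv,C_sas,R_sas,L_sas,C_sat,R_sat,L_sat,R_sar,R_scp,R_svn,C_svn
homma,sobol,3,7,1,2,8,9,19,13,10,17,16,18,14,6,12,15,5,4,20,11
homma,lattice,8,11,4,5,10,9,16,1,2,15,17,18,20,3,12,19,6,7,14,13
homma,golden,8,15,6,7,1,2,16,11,13,12,18,19,17,3,14,20,4,5,9,10
homma,uniform,2,1,6,7,12,11,18,13,14,3,20,16,17,4,15,19,9,10,5,8
homma,lhs,2,1,8,9,11,12,19,17,13,5,20,16,15,4,18,14,6,7,10,3
sobol,sobol,12,2,8,9,13,16,19,15,11,18,7,14,1,6,3,10,5,4,20,17
sobol,lattice,8,3,5,4,14,17,19,15,10,16,6,7,2,11,9,1,12,13,18,20
sobol,golden,13,3,8,6,7,18,15,20,12,17,4,14,2,9,5,1,11,10,16,19
sobol,uniform,9,5,8,6,2,14,20,18,7,10,17,4,1,12,19,3,16,15,11,13
sobol,lhs,11,5,8,9,14,15,13,20,10,18,16,12,1,7,6,2,3,4,19,17
jansen,sobol,5,1,3,2,7,18,8,16,4,17,9,6,15,10,13,14,12,11,19,20
jansen,lattice,5,1,3,2,7,18,8,16,4,17,9,6,15,10,11,14,13,12,19,20
jansen,golden,5,1,3,2,7,18,8,17,4,16,9,6,15,10,12,14,13,11,19,20
jansen,uniform,6,1,4,2,7,19,16,17,3,15,8,5,14,9,11,13,12,10,18,20
jansen,lhs,5,1,3,2,7,18,9,16,4,17,8,6,15,10,13,14,12,11,19,20
janon,sobol,5,1,3,2,7,18,8,16,4,17,9,6,15,10,13,14,12,11,19,20
janon,lattice,5,1,3,2,7,18,8,16,4,17,9,6,15,10,11,14,13,12,19,20
janon,golden,6,1,3,2,7,18,8,17,4,16,9,5,15,10,12,14,13,11,19,20
janon,uniform,6,1,4,2,7,19,16,17,3,15,8,5,14,9,10,13,12,11,18,20
janon,lhs,5,1,3,2,7,18,13,15,4,17,8,6,16,9,10,14,12,12,19,20
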