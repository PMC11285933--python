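estimator,sampler,tau_es,tau_ep,R_mv,Z_ao,R_s,C_sa,C_sv,E_max,E_min
homma,sobol,3,1,4,2,5,9,8,6,7
homma,lattice,3,1,4,2,6,7,9,8,5
homma,golden,2,4,6,1,7,5,8,9,3
homma,uniform,5,2,8,6,7,3,9,4,1
homma,lhs,3,4,5,6,1,8,2,7,9
sobol,sobol,3,2,4,1,5,8,7,6,9
sobol,lattice,6,2,4,1,3,9,7,5,8
sobol,golden,3,2,5,1,6,7,8,4,9
sobol,uniform,1,3,5,2,4,8,7,6,9
sobol,lhs,7,1,4,2,3,6,8,5,9
jansen,sobol,5,2,3,1,4,9,7,6,8
jansen,lattice,5,2,3,1,4,9,7,6,8
jansen,golden,5,2,3,1,4,9,7,6,8
jansen,uniform,5,2,3,1,4,9,7,6,8
jansen,lhs,5,2,3,1,4,9,7,6,8
janon,sobol,5,2,3,1,4,9,7,6,8
janon,lattice,5,2,3,1,4,9,7,6,8
janon,golden,5,2,3,1,4,9,7,6,8
janon,uniform,5,2,3,1,4,9,7,6,8
janon,lhs,5,2,3,1,4,9,7,6,8
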