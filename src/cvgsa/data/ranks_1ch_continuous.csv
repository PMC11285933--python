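estimator,sampler,tau_es,tau_ep,R_mv,Z_ao,R_s,C_sa,C_sv,E_max,E_min
homma,sobol,5,4,9,3,2,8,7,6,1
homma,lattice,5,4,9,3,2,8,6,7,1
homma,golden,5,4,9,3,1,8,5,6,2
homma,uniform,7,4,9,3,1,8,5,6,2
homma,lhs,6,4,8,1,3,9,5,7,2
sobol,sobol,4,3,8,5,1,7,9,6,2
sobol,lattice,4,3,9,6,1,8,7,5,2
sobol,golden,4,3,8,7,1,6,9,5,2
sobol,uniform,5,3,8,4,1,9,7,6,2
sobol,lhs,5,4,6,3,1,8,9,7,2
jansen,sobol,4,3,7,5,1,8,9,6,2
jansen,lattice,4,3,7,5,1,8,9,6,2
jansen,golden,4,3,7,5,1,8,9,6,2
jansen,uniform,4,3,7,5,1,8,9,6,2
jansen,lhs,4,3,7,5,1,8,9,6,2
janon,sobol,4,3,7,5,1,8,9,6,2
janon,lattice,4,3,7,5,1,8,9,6,2
janon,golden,4,3,7,5,1,8,9,6,2
janon,uniform,4,3,7,5,1,8,9,6,2
janon,lhs,4,3,7,5,1,8,9,6,2
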