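tissue,eps_inf,sigma_i,delta_eps_1,delta_eps_2,delta_eps_3,delta_eps_4,tau_1,tau_2,tau_3,tau_4,alpha_1,alpha_2,alpha_3,alpha_4
skin,4.0,0.0002,32.0,1100.0,0.0,0.0,7.23e-12,32.48e-9,159.15e-6,15.915e-3,0.0,0.2,0.2,0.2
fat,2.5,0.035,9.0,35.0,33000.0,10000000.0,7.96e-12,15.92e-9,159.15e-6,15.915e-3,0.2,0.1,0.05,0.01
muscle,4.0,0.2,50.0,7000.0,1200000.0,25000000.0,7.23e-12,353.68e-9,318.31e-6,2.274e-3,0.1,0.1,0.1,0.0
bone,2.5,0.02,10.0,180.0,5000.0,100000.0,13.26e-12,79.58e-9,159.15e-6,15.915e-3,0.2,0.2,0.2,0.0
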