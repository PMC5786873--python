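descriptor,unit,attractant_mean,attractant_sd,attractant_n,non_attractant_mean,non_attractant_sd,non_attractant_n,p_printed,d_printed
E,kJ/mol,-596.0,233.0,38,-566.0,186.0,15,0.7,0.14
E_sol,kJ/mol,-74.0,18.0,38,-61.0,16.0,15,0.02,0.76
E_H-E_L,eV,-10.6,1.0,38,-10.4,1.0,15,0.7,0.13
D,debye,2.5,1.1,38,1.8,0.7,15,0.009,0.67
q-,kJ/mol,-300.0,31.0,38,-269.0,36.0,15,0.003,0.96
q_ion-,kJ/mol,50.3,6.4,38,51.7,4.5,15,0.5,0.23
q+,kJ/mol,196.0,31.0,38,198.0,13.0,15,0.8,0.05
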