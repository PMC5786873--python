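serial_id,name,label,k_d,n_carboxyl,n_carbon,n_nh2,r_distance,sensitivity_printed
14,L-Aspartate,attractant,6e-08,2,2,1,2.950,7.2
35,DL-alpha-Methylaspartate,attractant,5e-07,2,2,1,2.958,6.3
36,DL-beta-Methylaspartate,attractant,3e-04,2,2,1,2.991,3.5
44,Oxaloacetate,non_attractant,,2,2,0,3.002,
37,N-Methyl-DL-aspartate,attractant,1e-03,2,2,0,3.006,3.0
13,D-Aspartate,attractant,1e-05,2,2,1,3.084,5.0
33,L-Malate,attractant,6e-04,2,2,0,3.151,3.2
27,DL-threo-beta-Hydroxyaspartate,attractant,1e-04,2,2,1,3.218,4.0
53,L-Glutamate,attractant,5e-06,2,3,1,3.269,5.3
2,N-Acetyl-L-aspartate,attractant,1e-03,2,2,0,3.282,3.0
22,Fumarate,attractant,3e-04,2,2,0,3.764,3.5
42,2-Methylsuccinate,attractant,5e-03,2,2,0,3.803,2.3
52,Succinate,attractant,2e-04,2,2,0,3.820,3.7
26,DL-erythro-beta-Hydroxyaspartate,attractant,5e-04,2,2,1,3.861,3.3
38,DL-alpha-Methylglutamate,non_attractant,,2,3,1,4.444,
31,alpha-Ketoglutarate,non_attractant,,2,3,0,5.063,
5,L-alpha-Aminoadipate,non_attractant,,2,4,1,6.358,
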