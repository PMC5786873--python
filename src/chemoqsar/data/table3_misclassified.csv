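serial_id,name,k_d,n_carboxyl,n_carbon
4,beta-Alanine,,1,
5,L-alpha-Aminoadipate,,2,4
8,gamma-Amino-n-butyrate,,1,
22,Fumarate,3e-4,2,2
24,L-Homocysteine,,1,
27,DL-threo-beta-Hydroxyaspartate,1e-4,2,2
33,L-Malate,6e-4,2,2
36,DL-beta-Methylaspartate,3e-4,2,2
38,DL-alpha-Methylglutamate,,2,3
42,2-Methylsuccinate,5e-3,2,2
52,Succinate,2e-3,2,2
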