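,E,E_aq,E_sol,M_W,E_H,E_L,E_H-E_L,D,A_CPK,PSA,V_CPK,O_CPK,AA,PA,q-,APA,q_ion-,q+,LogP,P
E,1.00,0.99,0.56,-0.77,0.48,0.68,-0.26,-0.14,-0.62,-0.70,-0.62,-0.58,-0.50,-0.69,-0.49,-0.66,-0.23,-0.59,0.12,-0.62
E_aq,0.99,1.00,0.64,-0.81,0.43,0.68,-0.29,-0.17,-0.66,-0.75,-0.66,-0.62,-0.54,-0.74,-0.46,-0.71,-0.21,-0.60,0.19,-0.66
E_sol,0.56,0.64,1.00,-0.73,-0.01,0.43,-0.26,-0.54,-0.63,-0.86,-0.63,-0.61,-0.55,-0.81,-0.04,-0.79,0.04,-0.49,0.74,-0.63
M_W,-0.77,-0.81,-0.73,1.00,-0.06,-0.47,0.33,0.41,0.95,0.82,0.95,0.92,0.88,0.87,0.16,0.81,0.14,0.42,-0.42,0.95
E_H,0.48,0.43,-0.01,-0.06,1.00,0.46,0.22,0.23,0.11,-0.16,0.11,0.11,0.22,-0.15,-0.76,-0.19,-0.27,-0.28,-0.19,0.12
E_L,0.68,0.68,0.43,-0.47,0.46,1.00,-0.61,-0.13,-0.29,-0.48,-0.30,-0.25,-0.23,-0.50,-0.54,-0.55,-0.17,-0.84,0.05,-0.32
E_H-E_L,-0.26,-0.29,-0.26,0.33,0.22,-0.61,1.00,0.18,0.34,0.25,0.34,0.31,0.40,0.28,0.02,0.34,0.16,0.50,0.03,0.39
D,-0.14,-0.17,-0.54,0.41,0.23,-0.13,0.18,1.00,0.39,0.42,0.39,0.34,0.37,0.49,-0.25,0.49,-0.09,0.13,-0.62,0.39
A_CPK,-0.62,-0.66,-0.63,0.95,0.11,-0.29,0.34,0.39,1.00,0.71,1.00,0.98,0.97,0.80,0.00,0.73,0.18,0.25,-0.36,0.99
PSA,-0.70,-0.75,-0.86,0.82,-0.16,-0.48,0.25,0.42,0.71,1.00,0.70,0.71,0.61,0.83,0.17,0.80,0.12,0.47,-0.65,0.70
V_CPK,-0.62,-0.66,-0.63,0.95,0.11,-0.30,0.34,0.39,1.00,0.70,1.00,0.97,0.97,0.80,0.01,0.73,0.17,0.25,-0.36,1.00
O_CPK,-0.58,-0.62,-0.61,0.92,0.11,-0.25,0.31,0.34,0.98,0.71,0.97,1.00,0.95,0.77,-0.03,0.69,0.15,0.21,-0.40,0.96
AA,-0.50,-0.54,-0.55,0.88,0.22,-0.23,0.40,0.37,0.97,0.61,0.97,0.95,1.00,0.71,-0.07,0.66,0.19,0.19,-0.32,0.97
PA,-0.69,-0.74,-0.81,0.87,-0.15,-0.50,0.28,0.49,0.80,0.83,0.80,0.77,0.71,1.00,0.19,0.97,0.10,0.41,-0.53,0.79
q-,-0.49,-0.46,-0.04,0.16,-0.76,-0.54,0.02,-0.25,0.00,0.17,0.01,-0.03,-0.07,0.19,1.00,0.28,0.19,0.47,0.28,0.02
APA,-0.66,-0.71,-0.79,0.81,-0.19,-0.55,0.34,0.49,0.73,0.80,0.73,0.69,0.66,0.97,0.28,1.00,0.16,0.45,-0.48,0.73
q_ion-,-0.23,-0.21,0.04,0.14,-0.27,-0.17,0.16,-0.09,0.18,0.12,0.17,0.15,0.19,0.10,0.19,0.16,1.00,-0.05,0.32,0.17
q+,-0.59,-0.60,-0.49,0.42,-0.28,-0.84,0.50,0.13,0.25,0.47,0.25,0.21,0.19,0.41,0.47,0.45,-0.05,1.00,-0.18,0.27
LogP,0.12,0.19,0.74,-0.42,-0.19,0.05,0.03,-0.62,-0.36,-0.65,-0.36,-0.40,-0.32,-0.53,0.28,-0.48,0.32,-0.18,1.00,-0.34
P,-0.62,-0.66,-0.63,0.95,0.12,-0.32,0.39,0.39,0.99,0.70,1.00,0.96,0.97,0.79,0.02,0.73,0.17,0.27,-0.34,1.00
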