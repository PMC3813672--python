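variable,simple_r,indirect,path
S,-0.83,-0.28,0.36
Na/K,-0.67,-0.03,-0.04
TN,-0.62,-0.04,0.04
Na,-0.55,0.46,0.54
PHA,-0.51,-0.06,-0.24
ORP,-0.38,-0.16,0.6
Mg,0.07,0.95,0.49
CO3,0.11,-1.7,-0.81
pH,0.47,0.23,0.71
K,0.48,0.21,-0.3
CIA,0.51,-0.07,0.1
HMi,0.54,-0.09,-0.09
wsK,0.73,-0.01,-0.02
SOM,0.74,0.18,0.2
neK,0.98,1.49,1.44
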