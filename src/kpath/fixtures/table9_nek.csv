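variable,simple_r,indirect,path
S,-0.86,0.19,-0.25
Na/K,-0.66,0.02,0.03
TN,-0.64,0.03,-0.03
Na,-0.61,-0.34,-0.37
PHA,-0.46,0.03,0.16
ORP,-0.41,0.10,-0.42
Mg,0.04,-0.67,-0.34
CO3,0.10,1.18,0.56
K,0.44,-0.14,0.2
pH,0.46,-0.16,-0.50
HMi,0.48,0.07,0.06
CIA,0.56,0.05,-0.07
wsK,0.77,0.01,0.01
SOM,0.8,-0.11,-0.14
eK,0.98,0.76,0.69
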