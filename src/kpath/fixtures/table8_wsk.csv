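variable,simple_r,indirect,path
PHA,-0.65,-0.32,-0.38
S,-0.56,0.17,-0.8
Na,-0.55,-1.15,-0.78
Na/K,-0.52,-0.01,-0.01
TN,-0.41,0.23,-0.38
ORP,-0.22,0.02,-1.28
Mg,-0.14,-0.79,-0.37
CO3,-0.07,-0.53,-0.24
pH,0.14,-0.35,-1.87
HMi,0.39,0.2,0.29
K,0.41,0.02,-0.01
CIA,0.47,2.02,-1.61
SOM,0.58,0.06,0.25
eK,0.73,0.05,0.14
neK,0.77,,
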