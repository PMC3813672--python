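var_a,var_b,r,flag
CIA,SOM,0.61,a
Na/K,SOM,-0.52,a
Na/K,CIA,0.829,b
TN,SOM,-0.61,a
wsK,SOM,0.58,a
wsK,Na/K,-0.52,a
neK,SOM,0.80,b
neK,CIA,0.56,a
neK,Na/K,-0.66,b
neK,TN,-0.64,b
neK,wsK,0.77,b
eK,SOM,0.74,b
eK,CIA,0.51,a
eK,Na/K,-0.67,b
eK,TN,-0.62,a
eK,wsK,0.73,b
eK,neK,0.98,b
bacteria,SOM,0.55,a
bacteria,neK,0.53,a
ORP,SOM,-0.59,a
ORP,TC,-0.56,a
ORP,TN,0.66,b
pH,SOM,0.58,a
pH,TC,0.66,b
pH,TN,-0.68,b
pH,ORP,-0.95,b
NHA,pH,-0.57,a
PHA,CIA,-0.51,a
PHA,Na/K,0.64,
PHA,wsK,-0.65,b
PHA,eK,-0.51,a
HMi,eK,0.54,a
HMc,HMi,0.93,b
CO3,CIA,-0.62,b
CO3,Na/K,0.56,
CO3,ORP,-0.50,a
K,CIA,0.53,a
K,Na/K,-0.79,b
K,PHA,-0.77,b
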