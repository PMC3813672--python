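group,TC,TN,SOM,PHA,NHA,HMi,HMc
NR1-16,4.51E-03,1.71E-03,7.88,4.53,2.59,1.47,0.92
R17-32,4.41E-03,5.74E-03,5.67,4.84,3.52,0.33,0.33
NR33-48,5.34E-03,2.02E-03,7.32,3.48,3.67,0.42,0.37
R49-64,3.74E-03,1.04E-02,5.54,4.11,2.55,0.45,0.32
N65-80,4.50E-03,1.64E-03,8.01,5.33,3.89,1.35,1.24
R81-96,3.64E-03,4.24E-03,5.79,5.26,4.58,0.42,0.23
NR97-112,3.01E-03,3.93E-03,8.53,3.62,3.28,0.66,0.41
R113-128,2.80E-03,1.31E-02,5.70,4.41,3.68,0.46,0.27
NR129-144,3.52E-03,3.46E-03,8.30,4.46,3.70,0.35,0.28
R145-160,3.22E-03,2.02E-02,5.38,5.00,3.82,0.30,0.30
NR161-176,3.18E-03,3.97E-03,7.84,4.90,1.75,0.88,0.45
R177-192,3.12E-03,2.31E-02,6.79,6.89,3.95,0.34,0.26
NR193-208,3.57E-03,3.24E-03,8.45,4.57,3.82,0.25,0.19
R209-224,3.79E-03,2.67E-02,5.79,5.43,4.22,0.44,0.36
NR225-240,4.30E-03,3.83E-03,8.01,4.94,4.61,0.52,0.32
R241-256,4.37E-03,2.75E-02,6.23,4.70,4.08,0.36,0.18
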