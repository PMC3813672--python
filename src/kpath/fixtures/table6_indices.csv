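group,ORP,pH,ba,Na/K,ICA,saf,CIA
NR1-16,17.30,7.27,0.45,0.29,1.03,8.73,76.08
R17-32,18.65,6.84,0.44,0.30,1.03,8.77,75.82
NR33-48,13.80,7.20,0.45,0.29,1.03,8.75,76.02
R49-64,30.24,6.5,0.45,0.30,1.04,8.74,75.95
N65-80,22.66,6.79,0.45,0.30,1.03,8.8,76.18
R81-96,22.68,6.73,0.48,0.32,1.08,8.86,75.08
NR97-112,10.22,6.94,0.44,0.30,1.03,8.78,76.21
R113-128,65.80,6.09,0.45,0.30,1.03,8.74,76
NR129-144,18.50,6.93,0.45,0.30,1.04,8.88,75.88
R145-160,80.84,5.79,0.46,0.31,1.04,8.90,75.67
NR161-176,31.46,6.48,0.44,0.29,1.02,8.80,76.16
R177-192,62.82,5.85,0.45,0.30,1.03,8.75,75.92
NR193-208,19.33,6.87,0.45,0.30,1.03,8.83,76.06
R209-224,52.48,6.19,0.45,0.31,1.04,8.86,75.76
NR225-240,13.72,6.98,0.45,0.30,1.03,8.83,75.99
R241-256,20.54,6.86,0.45,0.30,1.04,8.87,75.84
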