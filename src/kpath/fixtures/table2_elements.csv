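group,Na,Mg_a,Al,Si,Fe,Mg_b,Ca,P,CO3,S,Cl
NR1-16,0.44,0.39,6.49,36.86,3.35,1.49,0.37,491.01,49.74,219.34,119.8
R17-32,0.45,0.37,6.53,37.16,3.34,1.49,0.39,507.57,49.38,243.65,228.2
NR33-48,0.44,0.39,6.5,36.92,3.33,1.49,0.38,494.36,49.72,218.56,122.07
R49-64,0.44,0.39,6.51,36.94,3.34,1.49,0.39,483.04,49.64,251.93,217.78
N65-80,0.44,0.39,6.46,36.93,3.32,1.47,0.36,488.97,49.77,220.97,68.15
R81-96,0.47,0.42,6.3,36.38,3.29,1.46,0.4,515.89,50.45,248.77,80.32
NR97-112,0.44,0.38,6.49,37.04,3.35,1.48,0.37,506.34,49.62,218.38,82.48
R113-128,0.44,0.38,6.53,37.09,3.35,1.48,0.4,518.35,49.48,243.94,89.5
NR129-144,0.44,0.39,6.38,36.84,3.29,1.48,0.36,481.3,49.95,224.13,152.4
R145-160,0.45,0.39,6.39,36.94,3.27,1.47,0.38,512.73,49.84,237.7,201.2
NR161-176,0.43,0.38,6.49,37.09,3.32,1.49,0.37,484.59,49.58,225.39,142.88
R177-192,0.45,0.38,6.51,37.01,3.33,1.48,0.39,496.2,49.57,236.79,189.7
NR193-208,0.44,0.39,6.43,36.92,3.31,1.47,0.36,502.75,49.83,223.08,71.6
R209-224,0.45,0.38,6.43,37.08,3.32,1.46,0.39,491.22,49.64,245.74,81.48
NR225-240,0.44,0.38,6.46,37,3.31,1.47,0.38,509.11,49.7,228.9,90.5
R241-256,0.44,0.37,6.46,37.28,3.34,1.47,0.39,498.72,49.4,239.9,87.4
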