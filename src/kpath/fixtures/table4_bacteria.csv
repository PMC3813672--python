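group,bacteria_seedling,bacteria_budding,bacteria_wadding
NR1-16,0.8,2.1,1.6
R17-32,1.5,5.2,1.4
NR33-48,0.7,4.3,1.7
R49-64,1.1,3.4,1.9
N65-80,0.9,17,14
R81-96,1.0,87,30
NR97-112,1.2,26,19
R113-128,1.9,39,24
NR129-144,0.1,1.2,0.5
R145-160,0.4,1.3,0.7
NR161-176,0.9,4.3,2.2
R177-192,0.3,1.7,0.6
NR193-208,0.8,1.9,1.6
R209-224,0.7,7.1,4.0
NR225-240,0.1,2.3,0.9
R241-256,1.2,6.3,2.8
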