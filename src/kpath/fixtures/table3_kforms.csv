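group,K,wsK,neK,eK,wsK_weathered,neK_weathered,eK_weathered
NR1-16,14.93,27.1,134.9,58.64,67.57,174.48,62.9
R17-32,14.9,12.03,54.21,14.32,59.36,155.15,66.59
NR33-48,14.9,20.01,134.13,50.84,76.97,177.27,55.87
R49-64,14.87,9.22,58.27,12.21,123.72,170.67,71.24
N65-80,14.7,24.8,121.55,40.27,53.02,190.22,59.93
R81-96,14.57,5.65,39.17,6.28,61.31,153.27,57.35
NR97-112,14.75,41.28,101.36,27.46,56.24,167.15,69.44
R113-128,14.8,6.05,42.83,5.23,58.41,149.91,52.24
NR129-144,14.77,38.55,158.29,56.41,68.09,190.55,65.03
R145-160,14.73,15.92,78.62,23.18,60.89,167.13,52.79
NR161-176,14.87,88.78,162.24,61.11,70.46,181.02,55.25
R177-192,14.83,18.61,70.07,19.27,64.82,185.07,59.89
NR193-208,14.73,13.26,99.74,30.21,63.65,171.35,62.95
R209-224,14.63,6.41,38.74,7.63,61.96,162.21,52.09
NR225-240,14.73,25.27,105.8,29.54,64.59,182.24,59.77
R241-256,14.73,6.56,44.8,5.31,72.96,154.08,60.7
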