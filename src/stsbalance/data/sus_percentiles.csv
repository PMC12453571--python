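sus,percentile
0.0,0
51.6,14
51.7,15
62.6,34
62.7,35
64.9,40
65.0,41
71.0,59
71.1,60
72.5,64
72.6,65
74.0,69
74.1,70
77.1,79
77.2,80
78.8,84
78.9,85
80.7,89
80.8,90
84.0,95
84.1,96
100.0,100
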