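specimen_id,mpta,medial_slope,lateral_slope,torsion
1,0.25,1.42,3.03,6.18
2,0.46,0.45,0.89,6.81
3,0.83,0.97,0.95,3.12
4,0.28,1.97,0.02,5.64
5,0.94,0.40,1.39,4.62
6,0.85,0.79,0.61,5.66
7,0.14,1.19,1.44,12.67
8,0.85,0.79,0.61,4.89
9,0.41,0.98,2.20,1.16
10,0.31,0.37,0.63,11.63
11,0.84,1.69,1.88,2.84
12,0.78,1.39,1.52,5.52
13,0.63,0.35,1.27,3.91
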