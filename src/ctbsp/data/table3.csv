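subject,x_mm,y_mm,z_mm,dist_mm,i1_kg_cm2,i2_kg_cm2,i3_kg_cm2
1,-1.1,-0.1,16.0,16.0,0.23,0.46,0.47
2,0.0,0.0,18.2,18.2,0.23,0.46,0.47
3,-3.4,-0.3,13.9,14.3,0.21,0.54,0.58
4,0.3,0.4,16.1,16.1,0.20,0.40,0.41
5,-2.9,-0.1,17.6,17.8,0.27,0.65,0.69
6,-0.7,-0.3,15.8,15.9,0.26,0.52,0.53
7,-1.8,-1.3,17.0,17.1,0.23,0.54,0.55
8,-1.4,-0.4,19.3,19.3,0.26,0.62,0.63
9,-3.6,0.0,16.7,17.1,0.14,0.48,0.53
10,-1.4,-0.8,20.0,20.1,0.28,0.65,0.66
11,-2.2,-0.7,16.3,16.5,0.28,0.68,0.70
Mean,-1.7,-0.3,17.0,17.1,0.24,0.55,0.57
SD,1.3,0.5,1.7,1.7,0.04,0.09,0.10
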