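subject,x_mm,y_mm,z_mm,dist_mm
1,14.7,0.7,60.4,62.1
2,20.4,1.3,60.1,63.4
3,11.9,1.6,59.5,60.7
4,20.8,0.1,55.8,59.5
5,14.1,1.7,66.8,68.3
6,18.2,-0.6,62.3,64.9
7,17.1,-0.8,62.7,65.0
8,11.3,-1.2,67.5,68.5
9,7.3,2.3,66.3,66.8
10,9.8,0.3,67.7,68.4
11,9.4,-0.1,67.8,68.4
Mean,14.1,0.5,63.4,65.1
SD,4.6,1.1,4.1,3.3
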