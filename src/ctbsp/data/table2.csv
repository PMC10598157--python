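subject,x_mm,y_mm,z_mm,dist_mm,i1_kg_cm2,i2_kg_cm2,i3_kg_cm2
1,49.3,-0.4,9.3,50.2,38.55,69.53,72.03
2,45.5,-0.5,0.3,45.5,46.81,62.85,71.61
3,42.6,-0.5,10.0,43.8,32.84,50.84,54.00
4,42.7,-1.0,2.3,42.8,40.60,48.30,54.08
5,50.5,-5.7,11.8,52.2,83.11,139.00,161.16
6,39.2,-3.0,1.0,39.4,55.98,71.90,86.87
7,38.1,0.9,1.3,38.1,66.66,79.21,92.85
8,56.3,3.3,12.8,57.8,117.66,172.34,210.23
9,45.7,-3.7,15.4,48.3,45.03,99.44,114.32
10,49.6,-3.2,12.3,51.2,73.53,125.58,139.91
11,49.9,3.4,11.9,51.4,78.39,137.99,149.99
Mean,46.3,-0.9,8.0,47.3,61.74,96.09,109.73
SD,5.4,2.8,5.6,6.0,25.26,41.60,50.18
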