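subject,body_mass_kg,state,placement,voxel_x_mm,voxel_y_mm,voxel_z_mm
1,27,in_vivo,prone,0.47,0.47,1.00
2,29,in_vivo,prone,0.41,0.41,1.00
3,22,in_vivo,prone,0.49,0.49,0.70
4,18,in_vivo,prone,0.39,0.39,1.00
5,44,frozen,supine,0.53,0.53,0.60
6,31,thawed,supine,0.52,0.52,0.60
7,30,thawed,supine,0.54,0.54,0.60
8,48,frozen,supine,0.58,0.58,0.60
9,36,frozen,supine,0.55,0.55,0.60
10,39,frozen,supine,0.59,0.59,0.60
11,41,frozen,supine,0.59,0.59,0.60
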