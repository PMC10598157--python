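name,mean_hu,nominal_density_kg_m3
air,-1000.0,1.2
adipose,-80.0,950.0
water,0.0,1000.0
muscle,45.0,1060.0
trabecular,300.0,1160.0
cortical,1500.0,1800.0
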