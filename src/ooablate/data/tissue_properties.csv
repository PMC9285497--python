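name,density_kg_m3,electrical_conductivity_S_m,specific_heat_J_kgK,thermal_conductivity_W_mK,perfusion_coefficient_per_s,water_fraction
electrode,6450,1.0e8,840,18,0.0,0.0
plastic,70,1.0e-5,1045,0.026,0.0,0.0
nidus,1046,0.22,2726,0.56,0.0048,0.60
sclerotic,1908,0.0535,1313,0.32,0.000295,0.23
trabecular,1178,0.0867,2274,0.31,0.00059,0.27
cortical,1908,0.022,1313,0.32,0.0,0.23
muscle,1090,0.446,3421,0.49,0.00067,0.76
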