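load,macaque_fx_dz,macaque_fz_dx,macaque_my,human_fx_dz,human_fz_dx,human_my,ratio_fx_dz,ratio_fz_dx,ratio_my
Rt anterior temporalis,-1.59,0.03,-1.62,-5.31,-0.09,-5.22,3.34,-2.95,3.22
Rt posterior temporalis,-0.91,-0.07,-0.84,-3.60,-0.61,-2.99,3.96,8.68,3.57
Rt superficial masseter,-0.90,-0.02,-0.88,-3.39,-0.02,-3.37,3.77,1.21,3.83
Rt deep masseter,-0.69,-0.30,-0.39,-2.75,-0.43,-2.32,3.99,1.43,5.96
Rt medial pterygoid,-0.41,0.01,-0.42,-1.38,0.14,-1.52,3.37,13.84,3.62
Rt condyle,3.62,0.00,3.62,13.08,0.00,13.08,3.61,,3.61
Lt P3-M1 bite force,-0.55,0.21,-0.76,0.08,0.91,-0.84,-0.14,4.36,1.10
summed torques,-1.43,-0.14,-1.29,-3.29,-0.10,-3.19,2.30,0.68,2.47
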