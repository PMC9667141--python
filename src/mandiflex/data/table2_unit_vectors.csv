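muscle,side,homo_x,homo_y,homo_z,macaca_x,macaca_y,macaca_z,diff_x,diff_y,diff_z
anterior temporalis,L,1.00,0.07,0.01,0.96,-0.28,0.09,0.04,0.35,-0.08
anterior temporalis,R,1.00,0.09,-0.03,0.97,-0.22,0.03,0.03,0.31,-0.06
posterior temporalis,L,0.81,-0.56,0.19,0.65,-0.74,0.18,0.16,0.18,0.01
posterior temporalis,R,0.79,-0.57,-0.23,0.66,-0.75,-0.07,0.13,0.18,-0.16
deep masseter,L,0.94,0.03,0.34,0.72,-0.14,0.68,0.22,0.17,-0.34
deep masseter,R,0.90,0.20,-0.39,0.75,-0.04,-0.66,0.15,0.24,0.27
superficial masseter,L,0.96,0.21,0.20,0.79,0.49,0.36,0.17,-0.28,-0.16
superficial masseter,R,0.93,0.29,-0.24,0.85,0.31,-0.43,0.08,-0.02,0.19
medial pterygoid,L,0.75,0.36,-0.56,0.90,0.19,-0.38,-0.15,0.17,-0.18
medial pterygoid,R,0.78,0.41,0.48,0.89,0.17,0.43,-0.11,0.24,0.05
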