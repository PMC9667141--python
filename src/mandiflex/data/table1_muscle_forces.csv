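muscle,side,chew_side,Fx,Fy,Fz
anterior temporalis,L,left,58.4,3.8,0.7
anterior temporalis,R,left,80.4,6.9,-2.4
posterior temporalis,L,left,23.3,-16.1,5.4
posterior temporalis,R,left,53.1,-38.0,-15.6
deep masseter,L,left,8.2,0.3,3.0
deep masseter,R,left,40.1,9.0,-17.6
superficial masseter,L,left,107.7,23.8,22.5
superficial masseter,R,left,53.2,16.8,-13.9
medial pterygoid,L,left,58.1,28.0,-43.2
medial pterygoid,R,left,21.9,11.6,13.6
anterior temporalis,L,right,80.5,5.3,0.9
anterior temporalis,R,right,58.3,5.0,-1.7
posterior temporalis,L,right,54.2,-37.5,12.5
posterior temporalis,R,right,22.8,-16.3,-6.7
deep masseter,L,right,42.0,1.5,15.2
deep masseter,R,right,7.9,1.8,-3.5
superficial masseter,L,right,55.0,12.2,11.5
superficial masseter,R,right,104.2,32.9,-27.2
medial pterygoid,L,right,21.1,10.2,-15.7
medial pterygoid,R,right,60.2,31.8,37.3
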