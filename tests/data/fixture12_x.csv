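sample,g1,g2,g3
s1,-1.6,0.3,-0.5
s2,-0.8,-1.1,0.8
s3,0.9,0.7,-1.3
s4,-1.1,1.5,0.4
s5,0.7,-0.2,1.0
s6,-0.4,-0.8,-0.1
s7,1.2,-1.4,0.6
s8,-0.6,0.9,-0.9
s9,1.5,0.1,1.4
s10,0.3,-0.6,-0.2
s11,-0.9,1.2,0.5
s12,1.1,-1.0,-1.1
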