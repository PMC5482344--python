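drug,t1,t2,t3,t4
d1,1,1,?,1
d2,?,1,1,0
d3,1,?,?,0
d4,1,1,1,0
d5,0,1,?,1
d6,1,0,0,1
d7,1,1,1,1
d8,?,0,1,1
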