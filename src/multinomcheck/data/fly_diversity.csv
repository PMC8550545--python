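cell,count
c1,145
c2,96
c3,35
c4,29
c5,20
c6,11
c7,4
c8,4
c9,4
c10,3
c11,3
c12,2
c13,2
c14,1
c15,1
c16,1
c17,1
c18,1
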