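cell,count
T1,3416
T2,1912
T3,1748
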