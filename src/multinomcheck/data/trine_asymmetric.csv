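cell,count
T1,6192
T2,316
T3,248
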