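cell,count
A1A1,4
A1A2,33
A2A2,175
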