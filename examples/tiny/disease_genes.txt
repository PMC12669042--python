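P0005
P0001
P0000
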