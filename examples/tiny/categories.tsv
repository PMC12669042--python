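entity_id	category
M0	a
M1	a
M2	d
M3	d
M4	d
M5	d
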