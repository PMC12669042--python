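entity_id	entity_name	protein_id
M0	molecule-0	P0000
M0	molecule-0	P0001
M1	molecule-1	P0000
M1	molecule-1	P0005
M2	molecule-2	P0005
M2	molecule-2	P0007
M3	molecule-3	P0006
M3	molecule-3	P0007
M4	molecule-4	P0004
M4	molecule-4	P0006
M5	molecule-5	P0002
M5	molecule-5	P0004
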