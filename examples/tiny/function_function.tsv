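node_1	node_1_type	node_2	node_2_type
F001	biological_function	F000	biological_function
F002	biological_function	F000	biological_function
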