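node_1	node_1_type	node_2	node_2_type
P0000	protein	P0001	protein
P0000	protein	P0002	protein
P0000	protein	P0003	protein
P0001	protein	P0005	protein
P0001	protein	P0006	protein
P0002	protein	P0007	protein
P0003	protein	P0004	protein
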