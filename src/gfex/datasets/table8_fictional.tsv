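genome_id	c1	c2	c3	c4	c5
A	1	1	1	1	16
B	1	1	2	2	4
C	1	1	1	6	6
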