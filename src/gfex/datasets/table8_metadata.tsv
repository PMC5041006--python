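genome_id	size_mbp
A	1.5
B	1.0
C	2.0
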