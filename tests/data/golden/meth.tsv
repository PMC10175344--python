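probe_id	S001	S002
cg00000001	1234.5	10.0
cg00000002	60.25	3333.125
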