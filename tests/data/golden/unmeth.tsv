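probe_id	S001	S002
cg00000001	765.5	990.0
cg00000002	940.75	666.875
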