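sample_id	array_design	true_class	known_class	group	seizure_free	is_reference
S001	A450	classA	classA	classA	1	0
S002	A850	classB		classB		0
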