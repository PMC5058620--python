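# definition_set	chain	cdr	start	end (inclusive, scheme positions)
north	H	1	27	38
north	H	2	56	65
north	H	3	105	117
north	L	1	27	38
north	L	2	56	65
north	L	3	105	117
chothia	H	1	27	35
chothia	H	2	57	64
chothia	H	3	107	116
chothia	L	1	27	36
chothia	L	2	56	63
chothia	L	3	105	116
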