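# element	radius_angstrom
C	1.7
N	1.55
O	1.52
S	1.8
H	1.2
P	1.8
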