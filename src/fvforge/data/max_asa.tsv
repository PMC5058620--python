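# residue	max_asa_A2 (empirical Gly-X-Gly reference)
A	121
C	148
D	187
E	214
F	228
G	97
H	216
I	195
K	230
L	191
M	203
N	187
P	154
Q	214
R	265
S	143
T	163
V	165
W	264
Y	255
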