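# name	kind	pattern	regions	note
n_glycosylation	regex	N.[ST]	all	N-linked glycosylation sequon Asn-X-Ser/Thr
deamidation	regex	N[GS]	all	asparagine deamidation
asp_isomerization	regex	D[GSTD]	all	aspartate isomerization
met_oxidation	regex	M	all	methionine oxidation (exposure-gated)
trp_oxidation	regex	W	all	tryptophan oxidation (exposure-gated)
glycation	regex	K[KE]	all	lysine glycation context
unpaired_cys	unpaired_cys	-	all	cysteine outside the canonical intra-domain pair
pyroglutamate	nterm	EQ	all	N-terminal Glu/Gln pyroglutamate formation
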