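motif	class	source_id
QQQPP	IgE_epitope	lmw_gs_epitope
PFSQQQQPV	coeliac_toxic	cd_motif_1
FSQQQQQPL	coeliac_toxic	cd_motif_2
QQPPFSQQQQPPFSQ	coeliac_toxic	cd_motif_3
QQPPFSQQQQPVLPQ	coeliac_toxic	cd_motif_4
LQLQPFPQPQLPYPQPQLPYPQPQLPYPQPQPF	coeliac_toxic	alpha2_gliadin_33mer
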