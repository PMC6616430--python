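stage	column	rows	half	codons	incoming	displaced	rule
columns	A	*	*	-	Val	Gly	column sectoring: Val/Ala/Asp along columns 1-3, Gly retains column 4
columns	G	*	*	-	Ala	Gly	column sectoring
columns	U	*	*	-	Asp	Gly	column sectoring
split8	A	A,G	*	-	Leu	Val	third-position purine/pyrimidine split; incumbent keeps pyrimidine rows
split8	G	A,G	*	-	Pro	Ala	third-position purine/pyrimidine split
split8	C	A,G	*	-	Arg	Gly	third-position purine/pyrimidine split
split8	U	*	B	-	Glu	Asp	column 3 splits on the wobble half instead of rows
post_latch_16	A	U	*	-	Ile	Val	single-base third-position resolution
post_latch_16	G	U	*	-	Thr	Ala	single-base third-position resolution
post_latch_16	G	A	*	-	Ser	Pro	single-base third-position resolution
post_latch_16	U	U	A	-	Asn	Asp	single-base third-position resolution
post_latch_16	U	G	A	-	His	Asp	single-base third-position resolution
post_latch_16	U	U	B	-	Lys	Glu	single-base third-position resolution
post_latch_16	U	G	B	-	Gln	Glu	single-base third-position resolution
completion	A	U	B	AUG	Met	Ile	codon-level gain; cell 1-3B becomes mixed Ile/Met
completion	A	A	A	-	Phe	Leu	completion of row 1
completion	U	A	A	-	Tyr	Asp	completion of row 1
completion	U	A	B	-	STOP	Glu	stops confined to disfavored row 1
completion	C	U	A	-	Ser	Gly	Ser jump into the favored column; disconnected sector
completion	C	U	B	-	Arg	Gly	Arg gain from Gly
completion	C	A	A	-	Cys	Arg	completion of row 1
completion	C	A	B	UGA	STOP	Arg	codon-level; cell 4-1B becomes mixed STOP/Trp
completion	C	A	B	UGG	Trp	Arg	codon-level; cell 4-1B becomes mixed STOP/Trp
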