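clade	repeat	n_species	note
Chordata	AACCCT	21	DToL chromosomal assemblies; canonical form of TTAGGG
Arthropoda	AACCT	308	DToL chromosomal assemblies; most abundant repeat in the survey
Magnoliopsida	AAACCCT	19	DToL chromosomal assemblies; flowering-plant variant
Vespidae	AACCCAGACCC	4	conserved across Vespa, Vespula, Dolichovespula, Ancistrocerus
Bombus	AACCCG		compound repeat landscape; pasted with AACCT and AACCCT
Bombus	AACCT		compound repeat landscape; pasted with AACCCG and AACCCT
Bombus	AACCCT		compound repeat landscape; pasted with AACCCG and AACCT
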