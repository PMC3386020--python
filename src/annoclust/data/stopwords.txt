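hypothetical
uncharacterized
putative
contig
predicted
probable
fragment
genome
protein
chromosome
possible
similar to
proteins
homolog
possible
conserved
homologous
complete
shotgun
cdna
family
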