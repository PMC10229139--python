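gene_a	gene_b	directed
KLF1	GATA2	1
KLF1	RUNX1	1
GATA2	FLI1	1
GATA2	RUNX1	1
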