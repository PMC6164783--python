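# Default curated cis-regulatory element table (IUPAC patterns, PLACE-style).
name	pattern	category
ABRE	ACGTGGC	hormone
as-1/TGACG	TGACG	hormone
ERE	AWTTCAAA	hormone
W-box	TTGACC	pathogen
HSE	AGAANNTTCT	stress
LTR	CCGAAA	stress
MBS	CAACTG	stress
TC-rich	ATTTTCTTCA	stress
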