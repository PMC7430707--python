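name	iupac	functional_class
W-box	TTGACY	stress
ABRE	ACGTG	hormone
MBS	CAACTG	stress
LTR	CCGAAA	stress
ARE	AAACCA	stress
TC-rich	ATTTTCTTCA	stress
G-box	CACGTG	light
CAAT-box	CCAAT	promoter-core
TATA-box	TATAA	promoter-core
TGACG-motif	TGACG	hormone
CGTCA-motif	CGTCA	hormone
GARE-motif	TCTGTTG	hormone
TCA-element	CCATCTTTTT	hormone
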