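# Candidate regulator symbols (human) used as the default TF universe for
# network inference on real data. Synthetic runs pass the planted TF ids instead.
ZEB2
TBX21
PRDM1
LEF1
TCF7
EOMES
FOXO1
STAT4
ID2
ID3
BATF
IRF4
RUNX3
BACH2
TOX
NR4A1
NR4A2
KLF2
MYB
BCL6
GATA3
FOXP1
ZEB1
STAT1
STAT3
STAT5A
RORA
IKZF1
IKZF2
ETS1
ELK4
REL
RELA
NFATC1
NFKB1
JUN
JUNB
FOS
EGR1
EGR2
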