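gene	tpm
NOTCH1	4.1
NOTCH2	22
NOTCH3	45.3
TP53	32.4
CUL3	60.1
FAT1	14.9
ARID1A	19.7
KMT2D	12.6
AJUBA	12
PIK3CA	7.3
ARID2	7
NFE2L2	267.1
TP63	60.9
CCND1	78.9
ADAM29	0.0
GRM3	0.0
KCNH5	0.0
MUC17	0.0
PTPRT	0.0
SCN11A	0.0
SCN1A	0.0
SPHKAP	0.0
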