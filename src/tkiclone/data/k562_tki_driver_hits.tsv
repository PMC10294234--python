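gene	classification	samples	clinvar_id	vafs
ABL1	MISSENSE	lowN-R1		0.2648
AR	MISSENSE	highIM-R3		0.4655
BIRC6	MISSENSE	highIM-R4		0.2222
CACNA1D	MISSENSE	lowIM-R3;lowIM-R4		0.3429;0.4444
CREBBP	MISSENSE	lowN-R1		0.4066
EML4	MISSENSE	highIM-R4		0.3333
FAT3	MISSENSE	lowIM-R4		0.2526
IKBKB	MISSENSE	highIM-R1		0.5152
KAT6A	MISSENSE	highIM-R1;lowIM-R4;lowN-R2		0.3967;0.2611;0.4081
KLF5	MISSENSE	lowIM-R1		0.3077
KMT2D	MISSENSE	highN-R1		0.2481
KMT2D	MISSENSE	lowIM-R3;lowIM-R4		0.2043;0.2875
KMT2D	MISSENSE	highIM-R3	449928	0.371
KRAS	MISSENSE	highIM-R3	12581	0.6667
KRAS	MISSENSE	highIM-R4	12582	0.2927
LATS2	MISSENSE	lowN-R1		0.4286
LRP1B	MISSENSE	highIM-R1		0.3881
LRP1B	MISSENSE	highIM-R1		0.304
MAP2	MISSENSE	highN-R1		0.3333
MAP3K1	MISSENSE	lowN-R1		0.1667
MB21D2	MISSENSE	highN-R1		0.5682
MCM3AP	TRUNCATING	lowIM-R1		0.25
MYH9	MISSENSE	highN-R1		0.381
NRAS	MISSENSE	lowN-R2;highN-R2	73058	0.2917;0.3333
PDE4DIP	MISSENSE	lowN-R2;highN-R2		0.3;0.1961
PDGFRB	MISSENSE	highIM-R2		0.283
PRKCB	MISSENSE	highIM-R3		0.5152
PTPN11	MISSENSE	highIM-R2	13328	0.6929
RELA	MISSENSE	lowIM-R2;highIM-R2		0.2828;0.2923
SALL4	MISSENSE	highIM-R1		0.4322
SOX9	MISSENSE	highIM-R1		0.3066
TNC	MISSENSE	lowIM-R2;highIM-R2		0.2;0.2222
TP63	MISSENSE	lowIM-R1		0.4909
TP63	MISSENSE	highN-R1		0.1538
TRRAP	MISSENSE	lowN-R2;highN-R2		0.2993;0.2685
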