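# emforce network TSV
M	Gx	glucose (ext)	external
M	G	glucose	internal
M	M	branch intermediate	internal
M	P	product	internal
M	W	waste / biomass proxy	internal
M	Px	product (ext)	external
M	Wx	waste (ext)	external
R	UPT	-1000	0	-1 G + 1 Gx
R	R1	0	1000	-1 G + 1 M
R	R2	0	1000	-1 M + 1 P
R	R3	0	1000	-1 M + 1 W
R	EX_P	0	1000	-1 P + 1 Px
R	EX_W	0	1000	-1 W + 1 Wx
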