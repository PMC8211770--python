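code	Hex	Pent	dHex	HexA	terminal_class	trim_target	ms_terminals
G	0	0	0	0	-	-	-
X	0	1	0	0	-	-	Pent>G
L	1	1	0	0	Hex	X	Hex>X
F	1	1	1	0	dHex	L	dHex>L
S	0	2	0	0	-	-	Pent>X
D	0	2	0	0	-	-	Pent>X
E	0	2	1	0	dHex	D	dHex>D
B	0	2	0	0	-	-	Pent>X
Y	0	1	0	1	-	-	HexA>X
P	1	1	0	1	Hex	Y	Hex>Y;HexA>L
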