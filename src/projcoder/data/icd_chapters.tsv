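A00-B99	A00	B99
C00-D49	C00	D49
D50-D89	D50	D89
E00-E89	E00	E89
F01-F99	F01	F99
G00-G99	G00	G99
H00-H59	H00	H59
H60-H95	H60	H95
I00-I99	I00	I99
J00-J99	J00	J99
K00-K95	K00	K95
L00-L99	L00	L99
M00-M99	M00	M99
N00-N99	N00	N99
O00-O9A	O00	O9A
P00-P96	P00	P96
Q00-Q99	Q00	Q99
R00-R99	R00	R99
S00-T88	S00	T88
V00-Y99	V00	Y99
Z00-Z99	Z00	Z99
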