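region	residue	fraction
N	A	0.097800
N	C	0.039986
N	D	0.039986
N	E	0.039986
N	F	0.039986
N	G	0.082400
N	H	0.039986
N	I	0.039986
N	K	0.041000
N	L	0.039986
N	M	0.039986
N	N	0.039986
N	P	0.092200
N	Q	0.039986
N	R	0.124000
N	S	0.039986
N	T	0.039986
N	V	0.039986
N	W	0.039986
N	Y	0.002800
H	A	0.096800
H	C	0.031129
H	D	0.002100
H	E	0.031129
H	F	0.031129
H	G	0.031129
H	H	0.031129
H	I	0.031129
H	K	0.004100
H	L	0.369300
H	M	0.031129
H	N	0.003900
H	P	0.031129
H	Q	0.031129
H	R	0.031129
H	S	0.031129
H	T	0.031129
H	V	0.088000
H	W	0.031129
H	Y	0.031129
C	A	0.201400
C	C	0.035536
C	D	0.035536
C	E	0.035536
C	F	0.009900
C	G	0.161600
C	H	0.035536
C	I	0.035536
C	K	0.035536
C	L	0.035536
C	M	0.009000
C	N	0.010000
C	P	0.035536
C	Q	0.035536
C	R	0.035536
C	S	0.110600
C	T	0.035536
C	V	0.035536
C	W	0.035536
C	Y	0.035536
PLUS1	A	0.05
PLUS1	C	0.05
PLUS1	D	0.05
PLUS1	E	0.05
PLUS1	F	0.05
PLUS1	G	0.05
PLUS1	H	0.05
PLUS1	I	0.05
PLUS1	K	0.05
PLUS1	L	0.05
PLUS1	M	0.05
PLUS1	N	0.05
PLUS1	P	0.05
PLUS1	Q	0.05
PLUS1	R	0.05
PLUS1	S	0.05
PLUS1	T	0.05
PLUS1	V	0.05
PLUS1	W	0.05
PLUS1	Y	0.05
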