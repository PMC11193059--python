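<MASK>	0
A	1
C	2
D	3
E	4
F	5
G	6
H	7
I	8
K	9
L	10
M	11
N	12
P	13
Q	14
R	15
S	16
T	17
V	18
W	19
Y	20
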