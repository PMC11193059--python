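<MASK>	0
C	1
(	2
)	3
c	4
O	5
1	6
2	7
N	8
3	9
=	10
n	11
[	12
]	13
@	14
H	15
4	16
o	17
S	18
-	19
+	20
F	21
/	22
5	23
s	24
#	25
l	26
\	27
6	28
B	29
r	30
P	31
7	32
I	33
8	34
9	35
%	36
0	37
.	38
p	39
e	40
A	41
i	42
K	43
L	44
M	45
Z	46
a	47
g	48
u	49
t	50
T	51
*	52
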