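family	role	a1	a2	a3	a4
A	father	3	4
A	mother			4	15
A	juvenile		4	4
A	juvenile	3			15
A	juvenile		4		15
A	juvenile		4		15
A	juvenile	3			15
A	juvenile	3			15
A	juvenile	3		4
A	juvenile		4	4
A	juvenile	3			15
A	juvenile	3			15
A	juvenile	3		4
A	juvenile	3			15
A	juvenile		4		15
B	father	2	6
B	mother			1	8
B	juvenile		6	1
B	juvenile		6		8
B	juvenile		6	1
B	juvenile		6	1
B	juvenile		6		8
B	juvenile	2		1
B	juvenile		6		8
B	juvenile		6		8
B	juvenile	2		1
C	father	5	13
C	mother			2	8
C	juvenile		13	2
C	juvenile	5		2
C	juvenile	5		2
C	juvenile		13		8
C	juvenile	5			8
C	juvenile		13		8
C	juvenile		13		8
C	juvenile		13		8
C	juvenile	5			8
D	father	4	9
D	mother			6	16
D	juvenile	4		6
D	juvenile	4			16
D	juvenile		9		16
D	juvenile	4		6
D	juvenile		9		16
D	juvenile		9	6
D	juvenile		9	6
D	juvenile	4			16
E	father	2	6
E	mother			1	11
E	juvenile		6		11
E	juvenile	2			11
E	juvenile		6	1
E	juvenile	2			11
E	juvenile		6	1
E	juvenile	2		1
E	juvenile	2		1
E	juvenile	2			11
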