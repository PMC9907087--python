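# transcribed pattern-frequency data of the learning-motivation study appendix
# column order follows the printed table; verified against the printed marginals
# items: e1,e2,e3,e4,e5
pattern	frequency
00000	233
00001	46
00010	44
00011	28
00100	100
00101	32
00110	118
00111	110
01000	2
01001	1
01010	4
01011	4
01100	7
01101	5
01110	30
01111	31
10000	5
10010	4
10011	6
10100	12
10101	7
10110	18
10111	26
11000	1
11010	1
11011	3
11100	7
11101	7
11110	23
11111	113
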