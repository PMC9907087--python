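# transcribed pattern-frequency data of the learning-motivation study appendix
# column order follows the printed table; verified against the printed marginals
# items: i1,i2,i3,i4,i5
pattern	frequency
00000	360
00001	3
00010	4
00100	2
00101	1
00111	2
01000	34
01001	6
01010	1
01011	1
01100	1
01110	1
01111	3
10000	3
10011	1
10101	1
10111	4
11000	7
11001	3
11010	3
11011	16
11100	6
11101	2
11110	5
11111	478
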