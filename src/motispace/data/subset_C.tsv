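# transcribed pattern-frequency data of the learning-motivation study appendix
# column order follows the printed table; verified against the printed marginals
# items: j1,j2,j3,j4,d5,e1,e2,e5
pattern	frequency
00000000	273
00000001	19
00000010	11
00000011	2
00000100	14
00000101	1
00000110	7
00000111	2
00001000	2
00001001	3
00001101	1
00001110	1
00001111	1
00010000	4
00010001	1
00010110	1
00010111	1
00011011	1
00011110	1
00100000	2
00100001	2
00100100	1
00110001	1
00111111	1
01000000	20
01000001	2
01000010	1
01000100	2
01010000	15
01010010	1
01010110	1
01011001	1
01011011	1
01011110	1
01101001	2
01110000	1
01110001	1
01111111	1
10000000	29
10000001	10
10000010	3
10000011	2
10000100	3
10000101	1
10000110	1
10000111	1
10001000	8
10001001	4
10001100	1
10001101	1
10010000	2
10010001	1
10010110	1
10011001	1
10011011	1
10100000	1
10100001	4
10100010	1
10100100	1
10101001	4
10101011	1
10101111	1
10110001	3
10110100	1
10111001	5
10111011	1
10111111	1
11000000	14
11000001	1
11000010	1
11000011	3
11000100	2
11000101	1
11000110	1
11001000	4
11001001	1
11001011	1
11001100	1
11001110	1
11001111	1
11010000	3
11010001	4
11010010	1
11010100	1
11010111	2
11011000	3
11011001	1
11011011	1
11011100	1
11011110	2
11011111	2
11100000	2
11100001	4
11100111	1
11101000	2
11101001	8
11101010	1
11101011	1
11101101	2
11101111	4
11110000	3
11110001	16
11110011	1
11110100	2
11110101	1
11110111	1
11111000	5
11111001	25
11111010	2
11111011	12
11111100	1
11111101	11
11111110	1
11111111	50
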