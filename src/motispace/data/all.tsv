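# transcribed pattern-frequency data of the learning-motivation study appendix
# column order follows the printed table; verified against the printed marginals
# items: i1,i2,i3,i4,i5,j1,j2,j3,j4,d1,d2,d3,d4,d5,e1,e2,e3,e4,e5
pattern	frequency
0000000000000000000	15
0000000000000000010	3
0000000000000000100	3
0000000000000000110	7
0000000000000000111	1
0000000000000001100	2
0000000000000001110	1
0000000000000011100	1
0000000000000011110	1
0000000000000100001	1
0000000000000100111	1
0000000000001000000	1
0000000000010000000	1
0000000000110011111	1
0000000001000000010	1
0000000001101000100	1
0000000001110000000	2
0000000001110010100	1
0000000001111010110	2
0000000001111111111	1
0000001001000000110	1
0000001001111000100	1
0000001011110000110	2
0000010000000001001	1
0000010000000001110	1
0000010001000000111	1
0000010001100110101	1
0000010001110001101	1
0000010001110011110	1
0000010001110100100	1
0000010001110100111	1
0000010001111001110	1
0000010111111000101	1
0000011001110010100	1
0000011011110010100	1
0000011101111111111	1
0000011111000111111	1
0000011111100111111	1
0001000001000001110	1
0100000000111000111	1
0100000101111000111	1
0100001000000000000	1
0100001011111111110	1
0100011000000000010	1
0100100001111000100	2
0100100001111110111	1
0100100011111011110	1
0100111001111111111	1
1000000000000000000	1
1000000010000101101	1
1101000001111001111	1
1101101011111000100	1
1101111011111111111	1
1101111101111000001	2
1101111101111110111	1
1110011111111111111	1
1111100000000000101	1
1111100000001000000	1
1111100001111000000	6
1111100001111000001	1
1111100001111000010	1
1111100001111000011	1
1111100001111000100	3
1111100001111000101	1
1111100001111010000	1
1111100001111010100	1
1111100001111100001	1
1111100101111000001	1
1111101000111000111	1
1111101001111000010	2
1111101001111001110	1
1111101101111100111	1
1111101111111111111	1
1111110000111000110	1
1111110000111100000	1
1111110001111000001	1
1111110001111000100	2
1111110001111100101	2
1111110010000100111	1
1111110011111000000	1
1111110101111101011	1
1111110111111000011	1
1111110111111000111	1
1111110111111100011	1
1111110111111100101	1
1111110111111100111	1
1111111000001000000	1
1111111001111000000	1
1111111001111000100	1
1111111001111100100	1
1111111011111000011	1
1111111011111000101	1
1111111100111110111	1
1111111101111100000	1
1111111101111111111	1
1111111110001101111	1
1111111111111000000	1
1111111111111000111	3
1111111111111010010	1
1111111111111010111	1
1111111111111100001	2
1111111111111100100	2
1111111111111100111	1
1111111111111101000	1
1111111111111101111	2
1111111111111110011	1
1111111111111110111	3
1111111111111111101	2
1111111111111111111	24
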