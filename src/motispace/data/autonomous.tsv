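# transcribed pattern-frequency data of the learning-motivation study appendix
# column order follows the printed table; verified against the printed marginals
# items: i1,i2,i3,i4,i5,d1,d2,d3,d4,d5
pattern	frequency
0000000000	89
0000000001	5
0000000010	1
0000000100	1
0000000110	1
0000001100	1
0000001111	1
0000010000	5
0000010001	2
0000010011	1
0000011000	7
0000011001	3
0000011010	1
0000011011	1
0000011100	21
0000011101	7
0000011110	12
0000011111	4
0000100000	1
0001010000	1
0001010010	1
0010100011	1
0100000000	5
0100001110	1
0100010000	1
0100011000	1
0100011110	6
0100011111	4
0100111110	3
0100111111	2
0101011100	1
0101111101	1
0110011110	1
0111000001	1
0111111111	1
1000000000	1
1000000001	1
1001111111	1
1011111111	1
1100000010	1
1100111110	1
1101011110	2
1101111110	4
1101111111	5
1110011111	3
1111000011	1
1111100000	5
1111100001	6
1111100010	3
1111100011	2
1111101110	4
1111101111	4
1111110010	1
1111110111	1
1111111000	1
1111111010	1
1111111101	1
1111111110	100
1111111111	137
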