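# transcribed pattern-frequency data of the learning-motivation study appendix
# column order follows the printed table; verified against the printed marginals
# items: j1,j2,j3,j4,e1,e2,e3,e4,e5
pattern	frequency
000000000	114
000000001	5
000000010	16
000000011	2
000000100	33
000000101	3
000000110	28
000000111	4
000001000	1
000001100	3
000001110	6
000001111	2
000010000	1
000010100	5
000010101	1
000010110	3
000010111	1
000011100	3
000011110	3
000011111	3
000100000	1
000100110	1
000101101	1
000111110	2
000111111	1
001000000	2
001000001	1
001000111	1
001010000	1
001100001	1
001111111	1
010000000	3
010000010	4
010000100	4
010000110	6
010000111	2
010001110	1
010001111	1
010010010	1
010010100	1
010100000	1
010100011	1
010100100	1
010100101	2
010100110	5
010101110	1
010111110	2
011000111	1
011100000	1
011111111	1
100000000	19
100000001	2
100000010	2
100000011	2
100000100	7
100000101	4
100000110	3
100000111	4
100001001	1
100001101	1
100001110	2
100010000	1
100010010	1
100010100	1
100010101	2
100011101	1
100011110	1
100100000	1
100100111	1
100110011	1
101000000	1
101000001	3
101000011	1
101000111	3
101001011	1
101011011	1
101100011	2
101100101	2
101100111	2
101101101	1
101110100	1
101111101	1
110000000	5
110000010	1
110000100	4
110000110	5
110000111	4
110001011	1
110001110	1
110001111	2
110010100	1
110010110	1
110011110	1
110011111	1
110100000	1
110100011	1
110100100	1
110100101	1
110100110	2
110100111	2
110101110	4
110101111	1
110110100	1
110110110	2
110111110	1
110111111	4
111000000	2
111000001	2
111000011	1
111000100	1
111000110	1
111000111	5
111001110	1
111001111	1
111010111	2
111011111	5
111100000	4
111100001	4
111100011	3
111100100	2
111100101	4
111100110	1
111100111	19
111101000	1
111101011	1
111101100	1
111101111	11
111110010	1
111110011	2
111110110	1
111110111	8
111111101	3
111111110	1
111111111	49
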