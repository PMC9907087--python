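# transcribed pattern-frequency data of the learning-motivation study appendix
# column order follows the printed table; verified against the printed marginals
# items: i1,i3,i4,i5,j1,j2,j3,j4,d5,e3,e4,e5
pattern	frequency
000000000000	32
000000000001	1
000000000010	8
000000000100	24
000000000110	29
000000000111	3
000000001001	1
000000001111	2
000000010111	1
000000100000	1
000000100111	1
000001000000	1
000001000100	3
000001000110	3
000001000111	2
000001001001	1
000001010110	4
000001011110	1
000001110000	1
000001110010	1
000010000001	1
000010000100	1
000010000101	2
000010000110	3
000010000111	1
000010001100	2
000010001101	1
000010001110	2
000010001111	2
000010010000	1
000010101111	1
000010110101	1
000011000010	1
000011000011	1
000011000100	1
000011000110	2
000011010100	1
000011011110	1
000011100110	1
000011100111	1
000011101110	1
000011101111	2
000011110110	1
000011111110	1
000011111111	3
000100000100	2
000100001111	1
000100010110	1
000111000110	1
000111001111	1
001000000110	1
001010000101	1
001010001101	1
001111001101	1
011111111011	1
100000000000	1
100000000100	1
100000000110	1
100000010110	1
100000011101	1
100010000010	1
100010111101	1
100011110011	1
101000000111	1
101011111111	1
101100000000	1
101101010100	1
101111011111	1
101111100001	2
101111101111	1
101111110000	1
110011011111	1
110011111111	1
111000000000	1
111011010110	1
111100000000	19
111100000001	1
111100000010	1
111100000011	1
111100000100	5
111100000101	3
111100000110	2
111100000111	1
111100001001	1
111100010000	1
111100100000	2
111100100001	1
111100111101	1
111101000000	1
111101000010	2
111101000110	1
111101000111	1
111101010000	1
111101101111	1
111101111111	1
111110000000	7
111110000001	1
111110000100	2
111110000110	1
111110001000	2
111110001101	2
111110010000	1
111110011111	1
111110101011	2
111110110011	1
111110110111	1
111110111011	1
111110111101	1
111110111111	1
111111000000	3
111111000100	1
111111001100	1
111111001101	1
111111010011	1
111111010101	1
111111010110	1
111111011110	1
111111011111	1
111111101000	1
111111101111	10
111111110000	2
111111110010	1
111111110111	7
111111111000	2
111111111001	2
111111111011	2
111111111100	2
111111111101	4
111111111110	1
111111111111	39
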