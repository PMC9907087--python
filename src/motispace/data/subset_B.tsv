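# transcribed pattern-frequency data of the learning-motivation study appendix
# column order follows the printed table; verified against the printed marginals
# items: i1,i2,i3,i4,i5,d1,d2,d3,d4
pattern	frequency
000000000	105
000000001	1
000000010	1
000000011	1
000000100	1
000000110	1
000000111	1
000001000	10
000001001	1
000001100	12
000001101	2
000001110	31
000001111	22
000010000	1
000101000	1
000101001	1
001010001	1
010000000	5
010000111	1
010001000	1
010001100	1
010001110	1
010001111	11
010011111	5
010101110	1
010111110	1
011001111	1
011100000	1
011111111	2
100000000	2
100111111	1
101111111	1
110000000	1
110000001	1
110001111	1
110010011	1
110011111	1
110101111	2
110111111	10
111001111	4
111100001	1
111101111	1
111110000	11
111110001	8
111110111	11
111111001	2
111111010	1
111111011	1
111111100	1
111111101	1
111111110	1
111111111	289
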