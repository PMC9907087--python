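# transcribed pattern-frequency data of the learning-motivation study appendix
# column order follows the printed table; verified against the printed marginals
# items: d1,d2,d3,d4,d5
pattern	frequency
00000	197
00001	26
00010	9
00011	8
00100	2
00101	1
00110	4
00111	2
01000	1
01001	1
01100	5
01101	1
01110	21
01111	24
10000	12
10001	4
10010	4
10011	1
10100	2
10101	2
10111	3
11000	21
11001	6
11010	8
11011	2
11100	37
11101	14
11110	339
11111	316
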