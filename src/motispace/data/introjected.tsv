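# transcribed pattern-frequency data of the learning-motivation study appendix
# column order follows the printed table; verified against the printed marginals
# items: j1,j2,j3,j4
pattern	frequency
0000	458
0001	21
0010	7
0011	3
0100	41
0101	33
0110	3
0111	8
1000	122
1001	14
1010	32
1011	18
1100	63
1101	54
1110	53
1111	238
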