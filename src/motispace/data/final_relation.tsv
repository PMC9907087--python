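# SYNTHETIC transcription: meshed overall co-occurrence relation, derived from a
# published figure (not a data table); pair (p, q) per line means p is possessed
# whenever q is; reflexive-transitive closure is taken on load.
# items: i1,i2,i3,i4,i5,d1,d2,d3,d4,d5,j1,j2,j3,j4,e1,e2,e3,e4,e5
d1	d2
d2	d3
d3	d1
i2	d4
d4	i2
i1	i3
i3	i4
i4	i5
i5	i1
j3	j4
j4	d5
d5	j3
e1	e2
e2	e1
d1	i2
i2	i1
e3	e4
e4	j1
j1	j2
j2	e5
e5	j3
j3	e1
i1	j1
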