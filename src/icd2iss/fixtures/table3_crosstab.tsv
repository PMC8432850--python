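manual_group	0-8	9-15	16-24	25-40	41-49	50-75
0-8	126	73	11	7	1	1
9-15	25	66	25	6	0	0
16-24	13	43	75	22	2	0
25-40	8	22	48	28	6	2
41-49	1	1	2	5	3	1
50-75	2	0	2	6	4	3
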