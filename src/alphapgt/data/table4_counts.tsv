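family	maternal_upstream_5p	maternal_in_gene	maternal_downstream_3p	paternal_upstream_5p	paternal_in_gene	paternal_downstream_3p
1	0	0	39	0	0	25
2	1	0	44	0	0	33
3	0	0	47	0	0	24
4	1	0	27	4	0	60
5	1	0	36	5	0	27
6	4	0	59	5	0	25
7	1	0	64	5	0	34
8	0	0	43	0	0	44
9	3	0	37	5	0	25
10	3	0	33	3	0	31
11	2	0	49	7	0	41
12	6	0	46	2	0	21
13	6	0	37	1	0	33
14	2	0	11	2	0	46
15	3	0	16	2	0	44
16	1	0	51	1	0	20
17	1	0	45	4	0	33
18	1	0	49	4	0	33
19	1	0	50	8	0	48
20	1	0	68	5	0	24
21	8	0	42	1	0	31
22	4	0	67	1	0	26
23	1	0	21	1	0	52
24	6	0	30	2	0	45
25	2	0	52	4	0	49
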