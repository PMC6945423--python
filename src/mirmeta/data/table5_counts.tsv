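study_id	specimen	tp	fp	fn	tn
GSE14936	tissue	8	7	2	2
GSE15008	tissue	44	1	143	187
GSE16512	serum	1	2	1	3
GSE17681	serum	7	1	10	18
GSE18692A	tissue	5	1	2	6
GSE18692B	tissue	10	11	3	2
GSE19945	tissue	15	0	5	8
GSE24709	serum	17	0	11	19
GSE27486	serum	11	10	12	13
GSE27705	tissue	19	1	1	9
GSE29248	tissue	3	0	3	6
GSE31568	serum	12	5	20	65
GSE33045	serum	12	7	0	1
GSE36681	tissue	16	1	87	102
GSE40738	serum	8	1	73	55
GSE46729	serum	5	1	19	23
GSE47525	tissue	7	1	11	13
GSE48414	tissue	120	0	34	20
GSE51853	tissue	120	0	4	5
GSE53882	tissue	11	1	386	150
GSE56036	tissue	25	1	3	26
GSE61741	serum	26	25	46	69
GSE68951	serum	92	1	111	11
GSE74190	tissue	36	1	30	43
GSE93300	tissue	8	0	1	4
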