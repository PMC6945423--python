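table_id	variable	level	n	mean	sd
table1	Tissue	LUAD	101	30.371	5.475
table1	Tissue	Noncancerous	101	22.908	3.728
table1	Gender	Male	56	29.923	5.567
table1	Gender	Female	45	28.609	5.879
table1	Age (years)	< 60	41	30.642	5.238
table1	Age (years)	>= 60	60	28.446	5.899
table1	Smoke	No	26	31.159	5.435
table1	Smoke	Yes	18	30.138	5.671
table1	Tumor size	<= 3 cm	53	25.041	4.651
table1	Tumor size	> 3 cm	48	34.082	1.343
table1	Vascular invasion	No	70	28.986	5.839
table1	Vascular invasion	Yes	31	30.130	5.441
table1	TNM	I-II	44	26.730	5.442
table1	TNM	III-IV	57	31.350	5.114
table1	Lymph node metastasis	No	45	26.478	5.243
table1	Lymph node metastasis	Yes	56	31.635	5.036
table1	Pathological grading	I	17	27.642	5.863
table1	Pathological grading	II	61	29.753	5.713
table1	Pathological grading	III	23	29.489	5.641
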