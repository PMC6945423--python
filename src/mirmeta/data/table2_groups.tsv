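table_id	variable	level	n	mean	sd
table2	Tissue	NSCLC	124	29.615	5.616
table2	Tissue	Noncancerous	124	22.859	3.669
table2	Gender	Male	74	30.144	5.497
table2	Gender	Female	50	28.833	5.755
table2	Age (years)	< 60	56	30.913	5.052
table2	Age (years)	>= 60	68	28.547	5.864
table2	Smoke	No	38	31.184	5.185
table2	Smoke	Yes	29	30.237	5.530
table2	Histological type	Adenocarcinoma	101	29.337	5.717
table2	Histological type	Squamous carcinoma	23	30.836	5.086
table2	Tumor size	<= 3 cm	60	24.995	4.570
table2	Tumor size	> 3 cm	64	33.947	1.620
table2	Vascular invasion	No	90	29.456	5.720
table2	Vascular invasion	Yes	34	30.037	5.391
table2	TNM	I-II	54	27.131	5.424
table2	TNM	III-IV	70	31.532	5.007
table2	Lymph node metastasis	No	56	26.621	5.128
table2	Lymph node metastasis	Yes	68	32.081	4.759
table2	Pathological grading	I	17	27.642	5.863
table2	Pathological grading	II	77	29.853	5.721
table2	Pathological grading	III	30	30.124	5.131
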