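table_id	variable	level	n	mean	sd
table4	Tissue	Lung cancer	784	14.332	1.042
table4	Tissue	Noncancerous	89	11.962	0.994
table4	Histological type	Adenocarcinoma	448	14.273	0.947
table4	Histological type	Squamous carcinoma	336	14.411	1.154
table4	Gender	Male	460	14.367	1.042
table4	Gender	Female	324	14.282	1.042
table4	Age (years)	<= 60	213	14.396	1.040
table4	Age (years)	> 60	546	14.297	1.055
table4	T	T1 + T2	654	14.358	1.038
table4	T	T3 + T4	127	14.232	1.051
table4	Nodes	No	509	14.315	1.050
table4	Nodes	Yes	260	14.408	1.006
table4	Metastasis	No	540	14.376	1.041
table4	Metastasis	Yes	21	14.302	1.029
table4	Pathologic stage	I-II	631	14.320	1.063
table4	Pathologic stage	III-IV	145	14.366	0.962
table4	Anatomic organ subdivision	L-Lower	112	14.285	1.029
table4	Anatomic organ subdivision	L-Upper	198	14.240	0.995
table4	Anatomic organ subdivision	R-Lower	160	14.390	1.073
table4	Anatomic organ subdivision	R-Middle	29	14.416	1.008
table4	Anatomic organ subdivision	R-Upper	249	14.359	1.026
table4	Tumor location	Peripheral	187	14.342	1.013
table4	Tumor location	Central	162	14.366	1.130
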