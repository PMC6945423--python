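table_id	variable	level	n	mean	sd
table3	Tissue	LUAD	448	14.273	0.947
table3	Tissue	Noncancerous	45	11.644	1.160
table3	Gender	Male	209	14.259	0.902
table3	Gender	Female	239	14.286	0.987
table3	Age (years)	<= 50	33	14.295	1.205
table3	Age (years)	> 50	396	14.257	0.932
table3	T	T1 + T2	388	14.294	0.954
table3	T	T3 + T4	57	14.203	0.871
table3	Nodes	No	293	14.252	0.966
table3	Nodes	Yes	146	14.349	0.892
table3	Metastasis	No	285	14.326	0.898
table3	Metastasis	Yes	19	14.404	1.027
table3	Pathologic stage	I-II	351	14.249	0.958
table3	Pathologic stage	III-IV	92	14.340	0.918
table3	Anatomic neoplasm subdivision	L-Lower	70	14.229	0.825
table3	Anatomic neoplasm subdivision	L-Upper	108	14.206	0.998
table3	Anatomic neoplasm subdivision	R-Lower	85	14.214	0.940
table3	Anatomic neoplasm subdivision	R-Middle	18	14.281	0.789
table3	Anatomic neoplasm subdivision	R-Upper	155	14.351	0.986
table3	Tumor location	Peripheral	113	14.309	0.940
table3	Tumor location	Central	54	14.429	1.051
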