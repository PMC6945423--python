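study_id	subset_label	disease_subset	specimen	n_case	mean_case	sd_case	n_control	mean_control	sd_control	scale_note
GSE14936		NSCLC	tissue	10	7.763	0.850	9	8.137	0.819	chip intensity; M column carried as arm mean
GSE15008		NSCLC	tissue	187	11.401	1.255	188	9.697	0.867	chip intensity; M column carried as arm mean
GSE16512		NSCLC	serum	3	-0.024	0.031	14	-0.338	0.231	chip intensity; M column carried as arm mean
GSE17681		NSCLC	serum	17	12.652	0.756	19	12.174	0.753	chip intensity; M column carried as arm mean
GSE18692	A	NSCLC	tissue	7	0.458	0.304	7	0.251	0.153	chip intensity (GPL4717); M column carried as arm mean
GSE18692	B	NSCLC	tissue	13	0.288	0.343	13	0.403	0.341	chip intensity (GPL4718); M column carried as arm mean
GSE19945		LUAD	tissue	20	-0.325	1.781	8	-2.799	0.554	chip intensity; M column carried as arm mean
GSE24709		NSCLC	serum	28	12.253	0.532	19	11.626	0.775	chip intensity; M column carried as arm mean
GSE27486		LUAD	serum	22	5.680	0.428	23	5.731	0.646	chip intensity; M column carried as arm mean
GSE27705		NSCLC	tissue	20	0.106	0.934	10	-1.187	0.196	chip intensity; M column carried as arm mean
GSE29248		LUAD	tissue	6	12.643	0.704	6	11.099	2.171	chip intensity; M column carried as arm mean
GSE31568		NSCLC	serum	32	12.173	0.607	70	11.847	0.972	chip intensity; M column carried as arm mean
GSE33045		LUAD	serum	12	12.618	1.642	8	13.291	1.223	RT-PCR panel; M column carried as arm mean
GSE36681		NSCLC	tissue	103	12.151	1.215	103	11.282	1.232	chip intensity; M column carried as arm mean
GSE40738		LUAD	serum	81	5.225	0.581	56	5.025	0.675	chip intensity; M column carried as arm mean
GSE46729		NSCLC	serum	24	4.530	0.227	24	4.423	0.215	chip intensity; M column carried as arm mean
GSE47525		LUAD	tissue	18	4.927	0.716	14	4.727	0.412	chip intensity; M column carried as arm mean
GSE48414		LUAD	tissue	154	-0.364	2.547	20	-3.548	2.166	chip intensity; M column carried as arm mean
GSE51853		LUSC	tissue	124	1.177	1.045	5	-1.459	0.381	chip intensity; M column carried as arm mean
GSE53882		NSCLC	tissue	397	1.245	0.446	151	1.172	0.428	chip intensity; M column carried as arm mean
GSE56036		LUAD	tissue	28	6.397	1.319	27	4.166	0.663	chip intensity; M column carried as arm mean
GSE61741		NSCLC	serum	72	12.342	0.656	94	12.302	0.514	chip intensity; M column carried as arm mean
GSE68951		NSCLC	serum	203	1.225	0.336	12	1.149	0.144	chip intensity; M column carried as arm mean
GSE74190		NSCLC	tissue	66	0.761	1.650	44	-3.404	2.568	chip intensity; M column carried as arm mean
GSE93300		LUAD	tissue	9	-6.044	0.938	4	-8.187	0.885	chip intensity; M column carried as arm mean
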