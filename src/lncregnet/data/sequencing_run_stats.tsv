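sample	replicate	clean_reads	clean_bases_gb	q30_percent	unique_mapped_reads
Control	Control-1	88164550	13.22	94.41	62694500
Control	Control-2	86521924	12.98	94.52	61446125
Control	Control-3	83148774	12.47	93.75	58180935
T1	T1-1	79309130	11.90	94.02	56587130
T1	T1-2	83815786	12.57	93.84	59614126
T1	T1-3	79157270	11.87	94.39	57026412
T4	T4-1	85038374	12.76	94.92	59222002
T4	T4-2	106167856	15.93	94.94	74975222
T4	T4-3	81013688	12.15	94.60	57424480
T8	T8-1	91647384	13.75	95.01	63164281
T8	T8-2	100562348	15.08	94.96	70323780
T8	T8-3	98028886	14.70	94.87	67817950
T12	T12-1	81109770	12.17	94.20	55789226
T12	T12-2	84645330	12.70	94.35	57825950
T12	T12-3	87720638	13.16	95.34	58759700
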