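patient_id	edss_at_lp	delta_edss	relapse_count	dmt_2y	dmt_5y	class_2y	class_5y	diagnosis
MS25	6	0	0	none	none	PP	PP	PPMS
MS26	1	1	1	I	death	M	death	RRMS
MS27	1	2.5	4	II	II	H	H	RRMS
MS28	1.5	5	3	I	II	M	H	RRMS
MS29	6	0	3	II	II	H	H	RRMS
MS30	1	0	1	I	I	M	M	RRMS
MS31	0	1	3	none	I	L	M	RRMS
MS32	1.5	0.5	1	I	I	M	M	RRMS
MS33	0	1	2	I	I	M	M	RRMS
MS34	0	0	0	none	none	L	L	RRMS
MS35	1	1	2	I	I	M	M	RRMS
MS36	1	0	0	none	none	L	L	RRMS
MS37	0	1	0	I	I	M	M	RRMS
MS38	1	0	2	I	I	M	M	RRMS
MS39	1.5	0	0	none	none	LB	LB	benign
MS40	1	0	1	none	none	LB	LB	benign
MS41	3.5	0	?	none	lost	lost	lost	RRMS
MS42	0	1	1	I	I	M	M	RRMS
MS43	4	0	?	I	I	M	M	RRMS
MS44	2	0	3	II	II	H	H	RRMS
MS45	0	0	0	none	none	L	L	RRMS
MS46	0	0	2	I	I	M	M	RRMS
MS47	2	0	4	II	II	H	H	RRMS
MS48	?	?	?	no_MS	no_MS	no_MS	no_MS	somatoform
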