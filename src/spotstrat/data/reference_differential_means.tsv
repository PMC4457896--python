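spot_id	mean_a	sd_a	mean_b	sd_b	significance	published_fold_change	published_direction
70	0.045	0.008	0.034	0.008	*	~	~
72	0.040	0.008	0.024	0.014	**	1.7	down_in_B
97	0.125	0.035	0.210	0.057	**	1.7	up_in_B
98	0.033	0.003	0.046	0.011	*	~	~
99	0.022	0.007	0.015	0.005	*	1.5	down_in_B
101	0.053	0.012	0.041	0.006	*	~	~
102	0.108	0.023	0.082	0.013	*	~	~
117	0.062	0.015	0.048	0.014	*	~	~
227	0.034	0.009	0.026	0.005	*	~	~
288	0.224	0.150	0.139	0.099	NS	1.6	down_in_B
289	0.121	0.025	0.214	0.082	*	1.7	up_in_B
469	0.123	0.048	0.190	0.0944	NS	1.5	up_in_B
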