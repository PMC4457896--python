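patient_id	cluster_two_spot	cluster_three_spot
MS25	Z	OUT
MS26	Z	B1
MS27	Z	B1
MS29	Z	B1
MS44	Z	B1
MS47	Z	B1
MS28	G	D1
MS35	Z	B1
MS30	Z	D1
MS31	G	D1
MS32	Z	D1
MS33	G	D1
MS37	G	D1
MS38	G	D1
MS42	G	D1
MS43	G	D1
MS46	G	D1
MS34	G	D1
MS36	G	D1
MS45	G	D1
MS39	G	C1
MS40	G	C1
MS41	G	C1
MS48	OUT	C1
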